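"""Replicate-pair permutation null for spurious heritable factors.

When p >> n, sampling error alone produces sizeable line-mean correlations
and hence apparently heritable factors.  The null keeps each trait's
replicate pairs intact but reassigns pairs to line labels independently
per trait: every per-trait marginal statistic (including single-trait
heritability) is preserved exactly while between-trait genetic covariance
is destroyed.  Observed heritable factors are retained as biological
signal only when their number of significant loadings (n_tt) exceeds the
null maximum, or when their count of outlier-associated significant traits
(n_ot) falls outside the central 95% of null factors with matching n_tt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FactorSummary, classify_factors
from .model import ModelSpec, fit_bsfg
from .outliers import count_not, panel_outlier_table
from .preprocess import scale_panel
from .simulate import ExpressionPanel

__all__ = [
    "NullEnsemble",
    "permute_replicate_pairs",
    "build_null",
    "retain_factors",
    "pairwise_line_mean_correlations",
]


def permute_replicate_pairs(panel: ExpressionPanel, seed: int) -> ExpressionPanel:
    """Shuffle each trait's replicate pairs across line labels.

    Pairs move together (replicate pairing is never broken), with an
    independent uniform permutation per trait, so the per-trait multiset of
    line means — and therefore every single-trait variance component — is
    unchanged.
    """
    if panel.n_samples % panel.n_lines != 0:
        raise ValueError("unbalanced design cannot be pair-permuted")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    arr = panel.line_rep_array()  # (L, m, p)
    L, m, p = arr.shape
    permuted = np.empty_like(arr)
    for t in range(p):
        permuted[:, :, t] = arr[rng.permutation(L), :, t]
    li = panel.line_index
    order = np.lexsort((panel.sample_rep, li))
    values = np.empty_like(panel.values)
    values[order] = permuted.reshape(L * m, p)
    return ExpressionPanel(
        values=values,
        sample_line=panel.sample_line.copy(),
        sample_rep=panel.sample_rep.copy(),
        trait_ids=panel.trait_ids.copy(),
    )


@dataclass
class NullEnsemble:
    """Heritable-factor (n_tt, n_ot) records from permuted datasets."""

    records: list[tuple[int, int]]  # (n_tt, n_ot) per null heritable factor
    n_perm: int
    min_support: int = 20
    ntt_window: int = 2

    @property
    def max_null_ntt(self) -> int:
        return max((r[0] for r in self.records), default=0)

    def n_ot_interval(self, n_tt: int) -> tuple[float, float] | None:
        """Central-95% interval of null n_ot conditional on n_tt.

        Null factors with exactly matching n_tt are used when at least
        ``min_support`` exist; otherwise the match widens to a +/-
        ``ntt_window`` band on n_tt.  Returns None when support is still
        insufficient (the caller treats the factor as indeterminate).
        """
        exact = [r[1] for r in self.records if r[0] == n_tt]
        if len(exact) >= self.min_support:
            vals = exact
        else:
            vals = [
                r[1] for r in self.records if abs(r[0] - n_tt) <= self.ntt_window
            ]
            if len(vals) < self.min_support:
                return None
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return float(lo), float(hi)


def build_null(
    panel: ExpressionPanel,
    spec: ModelSpec,
    n_perm: int = 20,
    seed: int = 0,
    loading_alpha: float = 0.005,
    h2_alpha: float = 0.01,
    min_support: int = 20,
) -> NullEnsemble:
    """Fit the factor model to ``n_perm`` pair-permuted datasets.

    Each permuted dataset goes through the identical pipeline as observed
    data (SD scaling, same ModelSpec, classification, trait-level outlier
    calls); only heritable factors (n_tt >= 2 and significant h2)
    contribute records.  Permutation and fit seeds derive from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    ss = np.random.SeedSequence(seed).spawn(n_perm)
    records: list[tuple[int, int]] = []
    for child in ss:
        perm_seed, fit_seed = (int(s) for s in child.generate_state(2) >> 1)
        permuted = permute_replicate_pairs(panel, perm_seed)
        scaled_sd = scale_panel(permuted, "sd")
        fit_spec = ModelSpec(
            **{**spec.__dict__, "seed": fit_seed}
        )
        samples = fit_bsfg(scaled_sd, fit_spec)
        summaries = classify_factors(samples, loading_alpha, h2_alpha)
        heritable = [s for s in summaries if s.heritable]
        if heritable:
            scaled_iqr = scale_panel(permuted, "iqr")
            table = panel_outlier_table(scaled_iqr)
            for s in heritable:
                s.n_ot = count_not(s, table, permuted.trait_ids)
                records.append((s.n_tt, s.n_ot))
    return NullEnsemble(records=records, n_perm=n_perm, min_support=min_support)


def retain_factors(
    observed: list[FactorSummary], null: NullEnsemble
) -> list[FactorSummary]:
    """Flag observed heritable factors that exceed the permutation null.

    Criterion 1: n_tt strictly exceeds the maximum n_tt among null
    heritable factors.  Criterion 2 (only when criterion 1 fails): n_ot
    falls outside the central 95% of null n_ot among factors with matching
    n_tt.  Factors without sufficient null support for criterion 2 are
    conservatively flagged indeterminate (not retained).  Non-heritable
    factors are never retained.
    """
    for s in observed:
        if not s.heritable:
            s.retained = False
            s.retention_reason = "not heritable"
            continue
        if s.n_tt > null.max_null_ntt:
            s.retained = True
            s.retention_reason = "n_tt exceeds null maximum"
            continue
        if s.n_ot is None:
            raise ValueError("n_ot must be filled before retention gating")
        interval = null.n_ot_interval(s.n_tt)
        if interval is None:
            s.retained = False
            s.retention_reason = "indeterminate: insufficient null support"
        elif not (interval[0] <= s.n_ot <= interval[1]):
            s.retained = True
            s.retention_reason = "n_ot outside null 95% interval"
        else:
            s.retained = False
            s.retention_reason = "within null range"
    return observed


def pairwise_line_mean_correlations(
    panel: ExpressionPanel,
) -> tuple[np.ndarray, dict]:
    """All p(p-1)/2 pairwise correlations of per-trait line means.

    These are the "genetic" correlations of the line-mean profiles across
    lines.  Returns the flat upper-triangle vector and a summary with the
    0.005/0.025/0.5/0.975/0.995 quantiles and the count of |r| > 0.5.
    """
    if panel.n_traits < 2:
        raise ValueError("need at least 2 traits")
    lm = panel.line_rep_array().mean(axis=1)  # (L, p)
    sd = lm.std(axis=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(f"trait {panel.trait_ids[bad[0]]!r} has zero line-mean variance")
    corr = np.corrcoef(lm.T)
    iu = np.triu_indices(panel.n_traits, k=1)
    r = corr[iu]
    summary = {
        "quantiles": {
            q: float(np.quantile(r, q)) for q in (0.005, 0.025, 0.5, 0.975, 0.995)
        },
        "n_abs_gt_0.5": int((np.abs(r) > 0.5).sum()),
        "n_pairs": int(r.size),
        "median": float(np.median(r)),
    }
    return r, summary
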