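"""Outlier-line detection on the IQR scale and extreme-value accounting.

A line is an outlier for a variable (an expression trait or a latent
factor) when three conjunctive criteria hold: (1) the mean of its
replicates deviates more than 3 IQR from the median of the line means;
(2) every replicate deviates more than 3 IQR from the median of all
observations; and (3) the replicates deviate in the same direction.
Criteria (2) and (3) screen out single-replicate technical artifacts so
that calls reflect genotype-level effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FactorSummary
from .model import PosteriorSamples
from .preprocess import ScaledPanel, scale_matrix_iqr

__all__ = [
    "OutlierCall",
    "ExtremeReduction",
    "find_outlier_lines",
    "panel_outlier_table",
    "factor_outlier_calls",
    "count_not",
    "extreme_reduction",
]


@dataclass(frozen=True)
class OutlierCall:
    variable: str  # trait or factor identifier
    line: int  # line index
    direction: str  # "above" | "below" the median
    line_mean_deviation: float  # IQR units on the line-mean scale
    replicate_deviations: tuple[float, ...]  # IQR units on the pooled scale


def find_outlier_lines(
    values: np.ndarray, variable: str = "", threshold: float = 3.0
) -> list[OutlierCall]:
    """Apply the 3-criterion IQR rule to one variable.

    ``values`` is an (n_lines, n_reps) array of raw measurements; the
    line-mean and pooled medians/IQRs are computed internally, so calls are
    invariant to positive affine transforms of the variable.  All
    comparisons are strict ("more than" 3 IQR).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2:
        raise ValueError("values must be (n_lines, n_reps)")
    n_lines, m = vals.shape
    if n_lines < 4:
        raise ValueError("need at least 4 lines for a meaningful IQR")
    lm = vals.mean(axis=1)
    med_lm = np.median(lm)
    q75, q25 = np.percentile(lm, [75, 25])
    iqr_lm = q75 - q25
    pooled = vals.ravel()
    med_p = np.median(pooled)
    q75p, q25p = np.percentile(pooled, [75, 25])
    iqr_p = q75p - q25p
    if iqr_lm <= 0 or iqr_p <= 0:
        raise ValueError(f"zero IQR for variable {variable!r}")

    dev_lm = (lm - med_lm) / iqr_lm
    dev_rep = (vals - med_p) / iqr_p
    calls = []
    for i in range(n_lines):
        if abs(dev_lm[i]) <= threshold:
            continue
        reps = dev_rep[i]
        if not np.all(np.abs(reps) > threshold):
            continue
        signs = np.sign(reps)
        if not (np.all(signs > 0) or np.all(signs < 0)):
            continue
        calls.append(
            OutlierCall(
                variable=variable,
                line=i,
                direction="above" if dev_lm[i] > 0 else "below",
                line_mean_deviation=float(dev_lm[i]),
                replicate_deviations=tuple(float(d) for d in reps),
            )
        )
    return calls


def panel_outlier_table(
    scaled: ScaledPanel, threshold: float = 3.0
) -> dict[str, list[OutlierCall]]:
    """Outlier calls per trait of an IQR-scaled panel.

    Returns only traits with at least one call.  Detection re-derives the
    line-mean and pooled reference scales per trait, so the panel's own
    scaling does not affect the calls.
    """
    panel = scaled.parent
    arr = panel.line_rep_array(scaled.values)  # (L, m, p)
    table: dict[str, list[OutlierCall]] = {}
    for t in range(scaled.n_traits):
        name = str(panel.trait_ids[t])
        calls = find_outlier_lines(arr[:, :, t], variable=name, threshold=threshold)
        if calls:
            table[name] = calls
    return table


def factor_outlier_calls(
    samples: PosteriorSamples, threshold: float = 3.0
) -> dict[int, list[OutlierCall]]:
    """Outlier calls per latent factor.

    Posterior means of the sample-level latent values are arranged as
    line/replicate pairs and passed through the same 3-criterion rule as
    observed traits.
    """
    Fbar = samples.posterior_mean_F()
    li = samples.line_index
    L = int(li.max()) + 1
    m = len(li) // L
    order = np.lexsort((np.arange(len(li)), li))
    out: dict[int, list[OutlierCall]] = {}
    for j in range(samples.k):
        pairs = Fbar[order, j].reshape(L, m)
        calls = find_outlier_lines(pairs, variable=f"factor{j}", threshold=threshold)
        if calls:
            out[j] = calls
    return out


def count_not(
    factor: FactorSummary,
    trait_outlier_table: dict[str, list[OutlierCall]],
    trait_ids: np.ndarray,
) -> int:
    """n_ot: significantly loading traits with at least one outlier line."""
    sig_names = {str(trait_ids[t]) for t in factor.significant_traits}
    return sum(1 for name in sig_names if trait_outlier_table.get(name))


@dataclass
class ExtremeReduction:
    """Extreme-value counts before/after factor adjustment."""

    obs_before: int
    obs_after: int
    obs_percent_reduction: float | None
    line_before: int
    line_after: int
    line_percent_reduction: float | None


def _pct(before: int, after: int) -> float | None:
    if before == 0:
        return None
    return 100.0 * (1.0 - after / before)


def extreme_reduction(
    before: ScaledPanel, after_matrix: np.ndarray, threshold: float = 3.0
) -> ExtremeReduction:
    """Count extreme values in observed vs factor-adjusted data.

    ``before`` is the IQR-scaled observed panel; ``after_matrix`` is the
    adjusted (common-component-removed) data, re-centered and re-scaled on
    its own median/IQR before counting so the comparison is like-for-like.
    Counts are reported at the observation level and at the line-mean
    level; a percent reduction is undefined (None) when the before count
    is zero.
    """
    if before.scale_kind != "iqr":
        raise ValueError("before panel must be IQR-scaled")
    after = scale_matrix_iqr(after_matrix)
    if after.shape != before.values.shape:
        raise ValueError("shape mismatch between observed and adjusted data")
    panel = before.parent
    obs_b = int((np.abs(before.values) > threshold).sum())
    obs_a = int((np.abs(after) > threshold).sum())
    lm_b = panel.line_rep_array(before.values).mean(axis=1)
    lm_a = panel.line_rep_array(after).mean(axis=1)
    line_b = int((np.abs(lm_b) > threshold).sum())
    line_a = int((np.abs(lm_a) > threshold).sum())
    return ExtremeReduction(
        obs_before=obs_b,
        obs_after=obs_a,
        obs_percent_reduction=_pct(obs_b, obs_a),
        line_before=line_b,
        line_after=line_a,
        line_percent_reduction=_pct(line_b, line_a),
    )
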