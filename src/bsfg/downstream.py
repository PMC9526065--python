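"""Directionality, outlier-trait association and factor-class comparisons.

A factor's direction is arbitrary (like an eigenvector), so each factor is
given an imposed direction by flipping loadings and latent values together
by the sign of the mean trait loading; the product F Lambda' is unchanged.
Factors with vs without outlier lines are compared on heritability,
loading-direction bias, n_tt and mean |significant loading| via two-sided
Wilcoxon rank-sum tests, and the prediction of trait-level outliers from
factor-level latent values is scored with a Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import FactorSummary
from .outliers import OutlierCall

__all__ = [
    "ClassComparison",
    "AssociationResult",
    "DeviationTally",
    "impose_directionality",
    "direction_bias",
    "deviation_tally",
    "outlier_association",
    "compare_factor_classes",
]


def impose_directionality(
    summary: FactorSummary, latent_values: np.ndarray | None = None
) -> tuple[FactorSummary, np.ndarray | None]:
    """Orient a factor so its mean trait loading is non-negative.

    Multiplies the loadings (and, when given, the latent values) by the
    sign of the mean loading over all p traits; an exact zero mean is a
    tie, recorded with sign +1 and no flip.  Idempotent.
    """
    mean_loading = float(summary.median_loadings.mean())
    sign = 1 if mean_loading >= 0 else -1
    summary.direction_sign = sign
    if sign < 0:
        summary.median_loadings = -summary.median_loadings
        if summary.median_line_values is not None:
            summary.median_line_values = -summary.median_line_values
        if latent_values is not None:
            latent_values = -latent_values
    return summary, latent_values


def direction_bias(summary: FactorSummary) -> tuple[float, float, float]:
    """Proportions of significant loadings positive/negative, and their max.

    A bias of 1 means every significantly loading trait moves in the same
    direction; 0.5 is a perfectly mixed factor.
    """
    if summary.n_tt < 1:
        raise ValueError("direction bias requires at least one significant loading")
    sig = summary.median_loadings[summary.significant_traits]
    pos = float(np.mean(sig > 0))
    neg = float(np.mean(sig < 0))
    return pos, neg, max(pos, neg)


@dataclass
class DeviationTally:
    """Counts of outlier deviations above/below the median."""

    factor_above: int
    factor_below: int
    trait_above: int
    trait_below: int


def deviation_tally(
    factor_calls: dict[int, list[OutlierCall]],
    summaries: list[FactorSummary],
    line_mean_iqr: np.ndarray,
    trait_outlier_table: dict[str, list[OutlierCall]],
    trait_ids: np.ndarray,
) -> DeviationTally:
    """Tally outlier deviation directions at factor and trait level.

    Factor level: each outlier latent line value counts once, by direction.
    Trait level: for every (factor, outlier line) pair, the IQR-scaled line
    means of the factor's significantly loading traits that have that line
    as an outlier, counted by sign.  ``line_mean_iqr`` is (n_lines, p).
    """
    fa = fb = ta = tb = 0
    by_index = {s.index: s for s in summaries}
    for j, calls in factor_calls.items():
        summ = by_index.get(j)
        if summ is None:
            continue
        for call in calls:
            if call.direction == "above":
                fa += 1
            else:
                fb += 1
            for t in summ.significant_traits:
                name = str(trait_ids[t])
                if any(
                    c.line == call.line for c in trait_outlier_table.get(name, [])
                ):
                    dev = line_mean_iqr[call.line, t]
                    if dev > 0:
                        ta += 1
                    else:
                        tb += 1
    return DeviationTally(
        factor_above=fa, factor_below=fb, trait_above=ta, trait_below=tb
    )


@dataclass
class AssociationResult:
    x: np.ndarray  # |line latent value| in IQR units
    y: np.ndarray  # fraction of the factor's significant traits outlying
    rho: float | None
    p_value: float | None


def outlier_association(
    summaries: list[FactorSummary],
    trait_outlier_table: dict[str, list[OutlierCall]],
    trait_ids: np.ndarray,
) -> AssociationResult:
    """Predict per-trait outlier frequency from latent line values.

    One point per (line, retained heritable factor): x is the magnitude of
    the line's latent value on the factor's IQR scale; y the fraction of the
    factor's significantly loading traits for which that line is an outlier.
    Spearman's rho is reported, or None when every y is identical.
    """
    xs: list[float] = []
    ys: list[float] = []
    for s in summaries:
        if not s.retained or not s.heritable or s.median_line_values is None:
            continue
        lv = s.median_line_values
        med = np.median(lv)
        q75, q25 = np.percentile(lv, [75, 25])
        iqr = q75 - q25
        if iqr <= 0:
            continue
        dev = np.abs(lv - med) / iqr
        sig_names = [str(trait_ids[t]) for t in s.significant_traits]
        if not sig_names:
            continue
        for line in range(len(lv)):
            hits = sum(
                1
                for name in sig_names
                if any(c.line == line for c in trait_outlier_table.get(name, []))
            )
            xs.append(float(dev[line]))
            ys.append(hits / len(sig_names))
    x = np.array(xs)
    y = np.array(ys)
    if x.size < 3:
        raise ValueError("need at least 3 (line, factor) points")
    if np.allclose(y, y[0]):
        return AssociationResult(x=x, y=y, rho=None, p_value=None)
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(x=x, y=y, rho=float(rho), p_value=float(p))


@dataclass
class ClassComparison:
    metric: str
    with_outliers: np.ndarray
    without_outliers: np.ndarray
    statistic: float | None
    p_value: float | None
    note: str | None = None


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact p-values for group sizes <= 10 without ties; otherwise the normal
    approximation with continuity correction and mid-rank ties.
    """
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_factor_classes(
    summaries: list[FactorSummary],
) -> list[ClassComparison]:
    """Compare heritable factors with vs without outlier lines.

    Metrics: heritability estimate, direction bias, n_tt and the mean
    absolute significant loading.  Requires n_ot/outlier information to be
    filled; only heritable factors enter.
    """
    heritable = [s for s in summaries if s.heritable]
    with_o = [s for s in heritable if s.outlier_lines]
    without_o = [s for s in heritable if not s.outlier_lines]

    def metrics(group: list[FactorSummary]) -> dict[str, np.ndarray]:
        return {
            "heritability": np.array([s.h2_estimate for s in group]),
            "direction_bias": np.array([direction_bias(s)[2] for s in group]),
            "n_tt": np.array([float(s.n_tt) for s in group]),
            "mean_abs_significant_loading": np.array(
                [
                    float(np.mean(np.abs(s.median_loadings[s.significant_traits])))
                    for s in group
                ]
            ),
        }

    mw, mo = metrics(with_o), metrics(without_o)
    empty = not with_o or not without_o
    out = []
    for name in mw:
        if empty:
            out.append(
                ClassComparison(
                    metric=name,
                    with_outliers=mw[name],
                    without_outliers=mo[name],
                    statistic=None,
                    p_value=None,
                    note="a class is empty; no test performed",
                )
            )
        else:
            stat, p = _rank_sum(mw[name], mo[name])
            out.append(
                ClassComparison(
                    metric=name,
                    with_outliers=mw[name],
                    without_outliers=mo[name],
                    statistic=stat,
                    p_value=p,
                )
            )
    return out
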