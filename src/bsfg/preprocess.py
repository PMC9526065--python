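"""Centering/scaling of expression panels and extreme-value accounting.

Two scales are used throughout: the z-score (SD) scale the factor model is
fit on, and the IQR scale (median-centered, divided by the trait-specific
interquartile range) on which extreme values and outlier lines are defined.
Quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ExpressionPanel

__all__ = [
    "ScaledPanel",
    "scale_panel",
    "scale_matrix_iqr",
    "line_means",
    "qq_fraction_within",
    "count_extreme",
]


@dataclass
class ScaledPanel:
    """A per-trait centered and scaled view of an :class:`ExpressionPanel`."""

    values: np.ndarray  # (n, p)
    scale_kind: str  # "sd" | "iqr"
    center: np.ndarray  # (p,)
    scale: np.ndarray  # (p,)
    parent: ExpressionPanel

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Invert the scaling; equals the parent values to tolerance."""
        return self.center + self.values * self.scale


def _centers_scales(values: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "sd":
        center = values.mean(axis=0)
        scale = values.std(axis=0, ddof=1)
    elif kind == "iqr":
        center = np.median(values, axis=0)
        q75, q25 = np.percentile(values, [75, 25], axis=0)
        scale = q75 - q25
    else:
        raise ValueError(f"unknown scale kind {kind!r}; use 'sd' or 'iqr'")
    return center, scale


def scale_panel(panel: ExpressionPanel, kind: str = "sd") -> ScaledPanel:
    """Center/scale each trait: mean/SD (``kind="sd"``) or median/IQR.

    Raises ``ValueError`` naming the first offending trait if its SD or IQR
    is zero (constant traits should be dropped by the caller).
    """
    center, scale = _centers_scales(panel.values, kind)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        name = panel.trait_ids[bad[0]]
        raise ValueError(
            f"trait {name!r} has zero {'SD' if kind == 'sd' else 'IQR'}; "
            "drop constant traits before scaling"
        )
    return ScaledPanel(
        values=(panel.values - center) / scale,
        scale_kind=kind,
        center=center,
        scale=scale,
        parent=panel,
    )


def scale_matrix_iqr(matrix: np.ndarray) -> np.ndarray:
    """Median/IQR-scale the columns of a bare matrix (e.g. adjusted data)."""
    matrix = np.asarray(matrix, dtype=float)
    center, scale = _centers_scales(matrix, "iqr")
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ValueError(f"column {bad[0]} has zero IQR")
    return (matrix - center) / scale


def line_means(scaled: ScaledPanel) -> np.ndarray:
    """Per-line replicate means of the scaled values, (n_lines, p).

    Rows follow ``scaled.parent.lines`` order. Requires a balanced design.
    """
    panel = scaled.parent
    if panel.n_samples % panel.n_lines != 0:
        raise ValueError("unbalanced replicate structure")
    arr = panel.line_rep_array(scaled.values)
    return arr.mean(axis=1)


def qq_fraction_within(
    observed_pooled: np.ndarray, reference_pooled: np.ndarray
) -> float:
    """Fraction of observed values inside the middle 95% of the reference.

    The reference interval is its empirical [2.5%, 97.5%] quantile range;
    for data matching the reference distribution the fraction is ~0.95,
    while heavier-than-normal tails push it below.
    """
    obs = np.asarray(observed_pooled, dtype=float).ravel()
    ref = np.asarray(reference_pooled, dtype=float).ravel()
    if obs.size == 0 or ref.size == 0:
        raise ValueError("observed and reference sequences must be nonempty")
    lo, hi = np.percentile(ref, [2.5, 97.5])
    return float(np.mean((obs >= lo) & (obs <= hi)))


def count_extreme(
    scaled: ScaledPanel, threshold: float = 3.0
) -> tuple[int, np.ndarray]:
    """Count IQR-scaled values strictly beyond ``threshold`` IQR of the median.

    Returns (total, per-trait counts). Only defined on the IQR scale.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if scaled.scale_kind != "iqr":
        raise ValueError("extreme values are defined on the IQR scale")
    per_trait = (np.abs(scaled.values) > threshold).sum(axis=0)
    return int(per_trait.sum()), per_trait
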