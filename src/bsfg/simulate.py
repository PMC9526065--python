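"""Synthetic line-structured expression panels with planted factor structure.

The generator mirrors the generative model the sampler assumes: a small
number of latent factors, each with a factor heritability h2 (proportion of
the factor's unit variance attributable to among-line differences), sparse
trait loadings, trait-specific variances with their own heritabilities, and
optionally rare lines whose line-level latent value is shifted by several
latent-SD units ("planted outliers").  Every panel comes with its ground
truth so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ExpressionPanel",
    "PlantedOutlier",
    "simulate_expression",
    "simulate_normal_reference",
]


@dataclass(frozen=True)
class PlantedOutlier:
    """A rare large-effect genotype: a shift on one factor's line value.

    ``magnitude`` is in latent-SD units (the factor's total variance is 1),
    applied to the line-level genetic value so both replicates deviate
    consistently.
    """

    factor: int
    line: int
    magnitude: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("outlier magnitude must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("outlier sign must be -1 or +1")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic expression panel.

    Defaults follow the study design the package targets: 30 inbred lines
    with 2 biological replicates each (60 samples) and 3,385 expression
    traits.  ``factor_h2`` gives one heritability per true factor;
    ``loading_density`` is the proportion of traits with a nonzero loading
    on each factor and ``loading_scale`` the SD of those nonzero loadings.
    Trait-specific variances psi and their heritabilities are drawn
    uniformly from ``psi_range`` / ``psi_h2_range``.  ``tail_model`` is
    either ``"normal"`` or ``"t"`` (scaled Student-t residuals on the
    trait-specific deviations only, df ``t_df``).
    """

    n_lines: int = 30
    n_reps: int = 2
    n_traits: int = 3385
    k_true: int = 3
    factor_h2: Sequence[float] = (0.3, 0.6, 0.9)
    loading_density: float = 0.5
    loading_scale: float = 0.4
    psi_range: tuple[float, float] = (0.3, 0.8)
    psi_h2_range: tuple[float, float] = (0.0, 0.5)
    outliers: tuple[PlantedOutlier, ...] = ()
    tail_model: str = "normal"
    t_df: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_reps < 1 or self.n_traits < 1:
            raise ValueError("n_lines, n_reps and n_traits must be positive")
        if self.k_true < 0:
            raise ValueError("k_true must be non-negative")
        if len(self.factor_h2) != self.k_true:
            raise ValueError("factor_h2 must have length k_true")
        for h2 in self.factor_h2:
            if not (0.0 <= h2 <= 1.0):
                raise ValueError(f"factor_h2 entries must lie in [0, 1], got {h2}")
        if not (0.0 < self.loading_density <= 1.0):
            raise ValueError("loading_density must lie in (0, 1]")
        if self.loading_scale <= 0 or not np.isfinite(self.loading_scale):
            raise ValueError("loading_scale must be positive and finite")
        lo, hi = self.psi_range
        if not (0 < lo <= hi) or not np.isfinite(hi):
            raise ValueError("psi_range must be a positive finite interval")
        lo, hi = self.psi_h2_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("psi_h2_range must lie within [0, 1]")
        if self.tail_model not in ("normal", "t"):
            raise ValueError("tail_model must be 'normal' or 't'")
        if self.tail_model == "t" and self.t_df <= 2:
            raise ValueError("t_df must exceed 2 so residual variance is finite")
        for o in self.outliers:
            if not (0 <= o.factor < max(self.k_true, 1)):
                raise ValueError(f"outlier factor index {o.factor} out of range")
            if not (0 <= o.line < self.n_lines):
                raise ValueError(f"outlier line index {o.line} out of range")


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic panel.

    ``true_sample_values`` holds the per-replicate latent factor values
    (line value plus replicate deviation) so factor-level outlier detection
    can be scored without refitting a model.
    """

    true_loadings: np.ndarray  # (p, k_true)
    true_line_values: np.ndarray  # (n_lines, k_true)
    true_sample_values: np.ndarray  # (n, k_true)
    true_factor_h2: np.ndarray  # (k_true,)
    true_psi: np.ndarray  # (p,)
    true_psi_h2: np.ndarray  # (p,)
    outlier_registry: tuple[PlantedOutlier, ...] = ()


@dataclass
class ExpressionPanel:
    """A samples x traits expression matrix with line/replicate structure."""

    values: np.ndarray  # (n, p)
    sample_line: np.ndarray  # (n,) line labels
    sample_rep: np.ndarray  # (n,) replicate labels
    trait_ids: np.ndarray  # (p,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_line = np.asarray(self.sample_line)
        self.sample_rep = np.asarray(self.sample_rep)
        self.trait_ids = np.asarray(self.trait_ids)
        n, p = self.values.shape
        if self.sample_line.shape != (n,) or self.sample_rep.shape != (n,):
            raise ValueError("sample_line / sample_rep must match the number of rows")
        if self.trait_ids.shape != (p,):
            raise ValueError("trait_ids must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel values must be finite")
        pairs = list(zip(self.sample_line.tolist(), self.sample_rep.tolist()))
        if len(set(pairs)) != n:
            raise ValueError("duplicated (line, replicate) pair in panel")
        _, counts = np.unique(self.sample_line, return_counts=True)
        if len(set(counts.tolist())) > 1:
            raise ValueError("every line must have the same replicate count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def lines(self) -> np.ndarray:
        """Unique line labels in first-appearance order."""
        _, idx = np.unique(self.sample_line, return_index=True)
        return self.sample_line[np.sort(idx)]

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def reps_per_line(self) -> int:
        return self.n_samples // self.n_lines

    @property
    def line_index(self) -> np.ndarray:
        """Integer line code per sample, in the order of :attr:`lines`."""
        lookup = {lab: i for i, lab in enumerate(self.lines.tolist())}
        return np.array([lookup[lab] for lab in self.sample_line.tolist()])

    def line_rep_array(self, matrix: np.ndarray | None = None) -> np.ndarray:
        """Reshape a (n, p) matrix to (n_lines, reps, p), replicates sorted."""
        mat = self.values if matrix is None else np.asarray(matrix)
        li = self.line_index
        order = np.lexsort((self.sample_rep, li))
        return mat[order].reshape(self.n_lines, self.reps_per_line, -1)


def _component_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_expression(config: SimConfig) -> tuple[ExpressionPanel, GroundTruth]:
    """Simulate a balanced line/replicate expression panel.

    Per factor j the line value is u_ij ~ N(0, h2_j) and the replicate
    deviation ~ N(0, 1 - h2_j), so each latent factor has unit variance and
    loadings sit on the correlation-like scale a variance-standardized fit
    assumes.  Trait values are mean + (latent factors) @ loadings^T +
    line-specific genetic deviation + replicate residual; with
    ``tail_model="normal"`` and no planted outliers each trait's marginal
    variance is sum_j lambda_ij^2 + psi_i.
    """
    L, m, p, k = config.n_lines, config.n_reps, config.n_traits, config.k_true
    n = L * m
    if n < 2 * max(k, 1):
        import warnings

        warnings.warn("fewer than 2*k_true samples; factor recovery will be poor")
    rngs = _component_rngs(
        config.seed, ["loadings", "factors", "psi", "specific", "means"]
    )

    h2 = np.asarray(config.factor_h2, dtype=float)
    lam = np.zeros((p, k))
    if k:
        rl = rngs["loadings"]
        mask = rl.random((p, k)) < config.loading_density
        lam = np.where(mask, rl.normal(0.0, config.loading_scale, (p, k)), 0.0)

    line_index = np.repeat(np.arange(L), m)
    rep_index = np.tile(np.arange(m), L)

    rf = rngs["factors"]
    u = rf.normal(0.0, np.sqrt(h2), (L, k)) if k else np.zeros((L, 0))
    for o in config.outliers:
        u[o.line, o.factor] += o.sign * o.magnitude
    eps_f = (
        rf.normal(0.0, np.sqrt(1.0 - h2), (n, k)) if k else np.zeros((n, 0))
    )
    f_samples = u[line_index] + eps_f

    rp = rngs["psi"]
    psi = rp.uniform(*config.psi_range, p)
    psi_h2 = rp.uniform(*config.psi_h2_range, p)

    rs = rngs["specific"]
    u_s = rs.normal(0.0, np.sqrt(psi_h2 * psi), (L, p))
    resid_sd = np.sqrt((1.0 - psi_h2) * psi)
    if config.tail_model == "normal":
        resid = rs.normal(0.0, 1.0, (n, p))
    else:
        # standardized t: unit variance, heavier tails on specific deviations
        df = config.t_df
        resid = rs.standard_t(df, (n, p)) * np.sqrt((df - 2.0) / df)
    specific = u_s[line_index] + resid * resid_sd

    means = rngs["means"].normal(0.0, 1.0, p)
    values = means + f_samples @ lam.T + specific

    panel = ExpressionPanel(
        values=values,
        sample_line=np.array([f"line{i + 1}" for i in line_index]),
        sample_rep=np.array([f"rep{r + 1}" for r in rep_index]),
        trait_ids=np.array([f"trait{t + 1}" for t in range(p)]),
    )
    truth = GroundTruth(
        true_loadings=lam,
        true_line_values=u,
        true_sample_values=f_samples,
        true_factor_h2=h2,
        true_psi=psi,
        true_psi_h2=psi_h2,
        outlier_registry=tuple(config.outliers),
    )
    return panel, truth


def simulate_normal_reference(
    n_traits: int, n_samples: int, seed: int
) -> np.ndarray:
    """I.i.d. standard-normal reference matrix (n_samples x n_traits).

    Used as the null comparator for QQ checks of pooled scaled values; it is
    centered/scaled downstream exactly like observed data.
    """
    if n_traits < 1 or n_samples < 1:
        raise ValueError("n_traits and n_samples must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.normal(0.0, 1.0, (n_samples, n_traits))
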