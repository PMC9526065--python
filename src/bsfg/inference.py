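"""Posterior significance machinery: local false sign rate and error rates.

The local false sign rate (LFSR) of a posterior is the probability of
assigning the wrong sign to an estimate: for sign-free parameters
(loadings) the fraction of draws equal to zero or on the opposite side of
zero from the posterior median; for non-negative parameters (grid-sampled
heritabilities) the fraction of draws exactly equal to zero.  LFSRs within
a family are corrected to average error rates, the cumulative mean of the
ascending-sorted LFSRs mapped back to input order — analogous to a
q-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PosteriorSamples

__all__ = ["FactorSummary", "lfsr", "average_error_rate", "classify_factors"]


@dataclass
class FactorSummary:
    """Per-factor posterior summary and classification flags.

    ``n_ot``, ``retained``, ``direction_sign`` and ``outlier_lines`` are
    filled by the outlier / randomization / downstream stages.
    """

    index: int
    median_loadings: np.ndarray  # (p,)
    loading_lfsr: np.ndarray  # (p,)
    loading_error_rate: np.ndarray  # (p,)
    significant_traits: np.ndarray  # indices of traits with s < loading_alpha
    n_tt: int
    supported: bool
    h2_estimate: float
    h2_lfsr: float
    h2_error_rate: float
    heritable: bool
    n_ot: int | None = None
    retained: bool | None = None
    retention_reason: str | None = None
    direction_sign: int = 1
    outlier_lines: list = field(default_factory=list)
    median_line_values: np.ndarray | None = None  # (n_lines,) latent line means


def lfsr(draws: np.ndarray, nonnegative: bool = False) -> float:
    """Local false sign rate of a single parameter's posterior draws.

    For sign-free parameters: (draws equal to zero + draws with sign
    opposite the median) / T; a median of exactly zero yields 0.5 (maximal
    sign uncertainty).  With ``nonnegative=True`` (heritabilities): the
    fraction of draws exactly equal to zero.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("empty draw sequence")
    if nonnegative:
        return float(np.mean(x == 0.0))
    med = np.median(x)
    if med == 0.0:
        return 0.5
    opposite = (x * np.sign(med)) < 0
    return float(np.mean(opposite | (x == 0.0)))


def _lfsr_columns(draws: np.ndarray) -> np.ndarray:
    """Vectorized sign-free LFSR over columns of a (T, q) draw matrix."""
    med = np.median(draws, axis=0)
    sign = np.sign(med)
    frac = np.mean((draws * sign < 0) | (draws == 0.0), axis=0)
    return np.where(med == 0.0, 0.5, frac)


def average_error_rate(lfsrs: np.ndarray) -> np.ndarray:
    """Cumulative-mean correction of a family of LFSRs.

    Sort ascending; the estimate at sorted position i receives the mean of
    the first i sorted values; results are mapped back to input order.
    Output never exceeds the input elementwise.
    """
    x = np.asarray(lfsrs, dtype=float)
    if x.size == 0:
        return x.copy()
    if np.any((x < 0) | (x > 1)):
        raise ValueError("LFSRs must lie in [0, 1]")
    order = np.argsort(x, kind="stable")
    sorted_x = x[order]
    cummean = np.cumsum(sorted_x) / np.arange(1, x.size + 1)
    out = np.empty_like(x)
    out[order] = cummean
    return out


def classify_factors(
    samples: PosteriorSamples,
    loading_alpha: float = 0.005,
    h2_alpha: float = 0.01,
) -> list[FactorSummary]:
    """Significance-test every factor's loadings and heritability.

    Loadings are tested two-tailed at average error rate s < ``loading_alpha``
    (corrected within each factor's p loadings); a factor is statistically
    supported when n_tt >= 2.  Heritability is tested one-tailed at
    s < ``h2_alpha``, corrected across the k factor heritabilities.  Both
    thresholds are strict.
    """
    T, p, k = samples.Lambda.shape
    h2_lfsrs = np.array(
        [lfsr(samples.h2_factors[:, j], nonnegative=True) for j in range(k)]
    )
    h2_err = average_error_rate(h2_lfsrs)
    # latent line values: line means of posterior-mean F
    Fbar = samples.posterior_mean_F()
    L = int(samples.line_index.max()) + 1
    counts = np.bincount(samples.line_index, minlength=L).astype(float)
    summaries = []
    for j in range(k):
        draws = samples.Lambda[:, :, j]
        l_lfsr = _lfsr_columns(draws)
        l_err = average_error_rate(l_lfsr)
        sig = np.flatnonzero(l_err < loading_alpha)
        med_load = np.median(draws, axis=0)
        line_vals = (
            np.bincount(samples.line_index, weights=Fbar[:, j], minlength=L) / counts
        )
        summaries.append(
            FactorSummary(
                index=j,
                median_loadings=med_load,
                loading_lfsr=l_lfsr,
                loading_error_rate=l_err,
                significant_traits=sig,
                n_tt=int(sig.size),
                supported=sig.size >= 2,
                h2_estimate=float(np.median(samples.h2_factors[:, j])),
                h2_lfsr=float(h2_lfsrs[j]),
                h2_error_rate=float(h2_err[j]),
                heritable=bool(sig.size >= 2 and h2_err[j] < h2_alpha),
                median_line_values=line_vals,
            )
        )
    return summaries
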