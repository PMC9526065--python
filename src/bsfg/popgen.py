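"""Mutation-selection-balance selection strength and chromosome tests.

Rare large-effect alleles observed once among the founding genomes of an
inbred-line panel imply an allele frequency q of roughly 1/(4 * n_lines)
(two outbred diploid founders per line).  Under mutation-selection balance
the selection coefficient needed to hold a recessive allele at frequency q
is s = mu / q^2 (mu the genic mutation rate); with additive (h = 0.5) or
fully dominant (h = 1) effects the allele is visible to selection in
heterozygotes and the standard approximations give s = 2 mu / q and
s = mu / q, i.e. selection 1/(2q)- to 1/q-fold weaker suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SelectionEstimate",
    "ChromosomeTest",
    "selection_coefficient",
    "allele_frequency_from_panel",
    "chromosome_chisq",
    "DEFAULT_CHROMOSOME_CLASSES",
]

DEFAULT_CHROMOSOME_CLASSES = ("X", "2L", "2R", "3L", "3R", "other")

_MODES = ("recessive", "additive", "dominant")


@dataclass(frozen=True)
class SelectionEstimate:
    q: float
    mu: float
    mode: str
    s: float


def selection_coefficient(q: float, mu: float, mode: str = "recessive") -> SelectionEstimate:
    """Selection strength maintaining allele frequency q under MSB.

    recessive: s = mu / q^2; additive (h=0.5): s = 2 mu / q; dominant
    (h=1): s = mu / q.  s decreases in q and increases in mu.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly within (0, 1)")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if mode == "recessive":
        s = mu / q**2
    elif mode == "additive":
        s = 2.0 * mu / q
    else:
        s = mu / q
    return SelectionEstimate(q=q, mu=mu, mode=mode, s=s)


def allele_frequency_from_panel(
    n_carrier_lines: int,
    n_lines: int,
    ploidy: int = 2,
    founders_per_line: int = 2,
) -> float:
    """Allele frequency implied by carrier counts in an inbred-line panel.

    Each line descends from ``founders_per_line`` outbred diploid founders,
    so a panel of L lines samples ploidy * founders_per_line * L founding
    genomes (30 lines -> ~120 genomes); q = carriers / genomes.
    """
    if not (0 <= n_carrier_lines):
        raise ValueError("carrier count must be non-negative")
    if n_lines < 1 or ploidy < 1 or founders_per_line < 1:
        raise ValueError("counts must be positive")
    genomes = ploidy * founders_per_line * n_lines
    if n_carrier_lines > genomes:
        raise ValueError("more carriers than founding genomes")
    return n_carrier_lines / genomes


@dataclass
class ChromosomeTest:
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    df: int
    p_value: float
    method: str  # "asymptotic" | "monte-carlo"


def chromosome_chisq(
    gene_labels: Sequence[str],
    background_counts: Mapping[str, int],
    seed: int = 0,
    n_mc: int = 10_000,
) -> ChromosomeTest:
    """Chi-square test of a gene set's chromosome distribution.

    Expected counts come from the background class proportions times the
    set size.  When any expected count is below 5 the p-value is computed
    by Monte Carlo (``n_mc`` multinomial draws from the background),
    otherwise from the asymptotic chi-square with df = classes - 1.
    """
    labels = list(gene_labels)
    if not labels:
        raise ValueError("empty gene set")
    classes = list(background_counts.keys())
    bg = np.array([background_counts[c] for c in classes], dtype=float)
    if np.any(bg < 0) or bg.sum() <= 0:
        raise ValueError("invalid background counts")
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels not covered by background: {sorted(unknown)}")
    props = bg / bg.sum()
    n = len(labels)
    obs = np.array([labels.count(c) for c in classes], dtype=float)
    exp = props * n
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(classes) - 1
    if np.any(exp < 5):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        draws = rng.multinomial(n, props, size=n_mc)
        stats_mc = ((draws - exp) ** 2 / exp).sum(axis=1)
        p = float((np.sum(stats_mc >= stat) + 1) / (n_mc + 1))
        method = "monte-carlo"
    else:
        p = float(stats.chi2.sf(stat, df))
        method = "asymptotic"
    return ChromosomeTest(
        observed={c: int(o) for c, o in zip(classes, obs)},
        expected={c: float(e) for c, e in zip(classes, exp)},
        statistic=stat,
        df=df,
        p_value=p,
        method=method,
    )
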