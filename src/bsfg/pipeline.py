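"""End-to-end orchestration: scale, fit, classify, gate, summarize.

``run_pipeline`` sequences the full analysis — SD scaling and model fit,
significance classification, trait- and factor-level outlier detection,
the replicate-pair permutation null with retention gating, imposed
directionality, extreme-value reduction accounting, the line-mean
correlation spectrum, factor-class comparisons and mutation-selection-
balance selection estimates — and returns a report bundle plus a
machine-readable manifest of every seed consumed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .downstream import (
    ClassComparison,
    DeviationTally,
    compare_factor_classes,
    deviation_tally,
    direction_bias,
    impose_directionality,
    outlier_association,
)
from .inference import FactorSummary, classify_factors
from .model import ModelSpec, PosteriorSamples, adjust_data, fit_bsfg
from .outliers import (
    ExtremeReduction,
    count_not,
    extreme_reduction,
    factor_outlier_calls,
    panel_outlier_table,
)
from .popgen import allele_frequency_from_panel, selection_coefficient
from .preprocess import line_means, scale_panel
from .randomization import (
    NullEnsemble,
    build_null,
    pairwise_line_mean_correlations,
    retain_factors,
)
from .simulate import ExpressionPanel, SimConfig, simulate_expression

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Full-run configuration; either a panel or a SimConfig as input."""

    input_panel: ExpressionPanel | None = None
    sim_config: SimConfig | None = None
    model_spec: ModelSpec = ModelSpec()
    n_perm: int = 20
    loading_alpha: float = 0.005
    h2_alpha: float = 0.01
    extreme_threshold: float = 3.0
    mu_range: tuple[float, float] = (1e-6, 1e-5)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_panel is None) == (self.sim_config is None):
            raise ValueError("provide exactly one of input_panel or sim_config")
        if self.loading_alpha <= 0 or self.h2_alpha <= 0 or self.extreme_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineReport:
    factor_table: pd.DataFrame
    summaries: list[FactorSummary]
    samples: PosteriorSamples
    trait_outliers: dict
    factor_outliers: dict
    null: NullEnsemble
    reduction: ExtremeReduction
    correlation_summary: dict
    class_comparisons: list[ClassComparison]
    tally: DeviationTally
    association_rho: float | None
    association_p: float | None
    selection_table: pd.DataFrame
    manifest: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.factor_table.to_csv(outdir / "factor_summaries.tsv", sep="\t", index=False)
        self.selection_table.to_csv(outdir / "selection_estimates.tsv", sep="\t", index=False)
        rows = [
            {
                "variable": c.variable,
                "line": c.line,
                "direction": c.direction,
                "line_mean_deviation": c.line_mean_deviation,
            }
            for calls in list(self.trait_outliers.values())
            + list(self.factor_outliers.values())
            for c in calls
        ]
        pd.DataFrame(rows).to_csv(outdir / "outlier_calls.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _factor_table(summaries: list[FactorSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        bias = direction_bias(s)[2] if s.n_tt >= 1 else np.nan
        rows.append(
            {
                "factor": s.index,
                "n_tt": s.n_tt,
                "n_ot": s.n_ot,
                "h2": s.h2_estimate,
                "h2_lfsr": s.h2_lfsr,
                "h2_error_rate": s.h2_error_rate,
                "supported": s.supported,
                "heritable": s.heritable,
                "retained": s.retained,
                "retention_reason": s.retention_reason,
                "direction_sign": s.direction_sign,
                "direction_bias": bias,
                "n_outlier_lines": len(s.outlier_lines),
                "outlier_lines": ",".join(str(c.line) for c in s.outlier_lines),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full analysis; deterministic given the config (incl. seed)."""
    root = np.random.SeedSequence(config.seed)
    fit_seed, null_seed = (int(s) for s in root.generate_state(2) >> 1)

    if config.sim_config is not None:
        panel, _truth = simulate_expression(config.sim_config)
    else:
        panel = config.input_panel
    assert isinstance(panel, ExpressionPanel)

    scaled_sd = scale_panel(panel, "sd")
    scaled_iqr = scale_panel(panel, "iqr")

    spec = dataclasses.replace(config.model_spec, seed=fit_seed)
    samples = fit_bsfg(scaled_sd, spec)
    summaries = classify_factors(samples, config.loading_alpha, config.h2_alpha)

    trait_table = panel_outlier_table(scaled_iqr, config.extreme_threshold)
    factor_calls = factor_outlier_calls(samples, config.extreme_threshold)
    for s in summaries:
        s.n_ot = count_not(s, trait_table, panel.trait_ids)
        s.outlier_lines = factor_calls.get(s.index, [])

    null = build_null(
        panel,
        config.model_spec,
        n_perm=config.n_perm,
        seed=null_seed,
        loading_alpha=config.loading_alpha,
        h2_alpha=config.h2_alpha,
    )
    retain_factors(summaries, null)

    for s in summaries:
        impose_directionality(s)

    adjusted = adjust_data(scaled_sd, samples)
    # back to the raw-data scale before re-scaling on median/IQR
    adjusted_raw = adjusted * scaled_sd.scale + scaled_sd.center
    reduction = extreme_reduction(scaled_iqr, adjusted_raw, config.extreme_threshold)

    _, corr_summary = pairwise_line_mean_correlations(panel)
    comparisons = compare_factor_classes(summaries)

    lm_iqr = line_means(scaled_iqr)
    retained_with_calls = {
        j: calls
        for j, calls in factor_calls.items()
        if any(s.index == j and s.retained for s in summaries)
    }
    tally = deviation_tally(
        retained_with_calls, summaries, lm_iqr, trait_table, panel.trait_ids
    )
    try:
        assoc = outlier_association(summaries, trait_table, panel.trait_ids)
        rho, pval = assoc.rho, assoc.p_value
    except ValueError:
        rho, pval = None, None

    # selection strength implied by the modal carrier count among outliers
    carrier_counts = [len(calls) for calls in retained_with_calls.values()] or [1]
    n_carriers = int(np.bincount(carrier_counts).argmax()) or 1
    q = allele_frequency_from_panel(n_carriers, panel.n_lines)
    sel_rows = []
    for mu in config.mu_range:
        for mode in ("recessive", "additive", "dominant"):
            est = selection_coefficient(q, mu, mode)
            sel_rows.append({"q": q, "mu": mu, "mode": mode, "s": est.s})
    selection_table = pd.DataFrame(sel_rows)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "fit_seed": fit_seed,
        "null_seed": null_seed,
        "n_perm": config.n_perm,
        "model_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.model_spec.__dict__.items()
        },
        "loading_alpha": config.loading_alpha,
        "h2_alpha": config.h2_alpha,
        "extreme_threshold": config.extreme_threshold,
        "n_lines": panel.n_lines,
        "n_traits": panel.n_traits,
    }
    return PipelineReport(
        factor_table=_factor_table(summaries),
        summaries=summaries,
        samples=samples,
        trait_outliers=trait_table,
        factor_outliers=factor_calls,
        null=null,
        reduction=reduction,
        correlation_summary=corr_summary,
        class_comparisons=comparisons,
        tally=tally,
        association_rho=rho,
        association_p=pval,
        selection_table=selection_table,
        manifest=manifest,
    )
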