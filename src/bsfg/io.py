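"""File formats: TSV panels, YAML configs, HDF5 posterior draws."""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import ModelSpec, PosteriorSamples
from .simulate import ExpressionPanel, GroundTruth, PlantedOutlier, SimConfig

__all__ = [
    "write_panel",
    "read_panel",
    "write_ground_truth",
    "read_sim_config",
    "write_sim_config",
    "read_model_spec",
    "write_model_spec",
    "write_posterior",
    "read_posterior",
]

_SAMPLE_RE = re.compile(r"^(?P<line>.+)_(?P<rep>rep\d+)$")


def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    """TSV with sample IDs "<line>_<rep>" in the first column."""
    ids = [f"{l}_{r}" for l, r in zip(panel.sample_line, panel.sample_rep)]
    df = pd.DataFrame(panel.values, index=ids, columns=panel.trait_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_panel(path: str | Path) -> ExpressionPanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lines, reps = [], []
    for sid in df.index.astype(str):
        m = _SAMPLE_RE.match(sid)
        if not m:
            raise ValueError(f"sample id {sid!r} is not of the form <line>_rep<r>")
        lines.append(m.group("line"))
        reps.append(m.group("rep"))
    return ExpressionPanel(
        values=df.to_numpy(dtype=float),
        sample_line=np.array(lines),
        sample_rep=np.array(reps),
        trait_ids=df.columns.to_numpy(),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Companion TSV: per-trait truth plus factor/outlier blocks as headers."""
    p, k = truth.true_loadings.shape
    df = pd.DataFrame(
        truth.true_loadings, columns=[f"loading_factor{j + 1}" for j in range(k)]
    )
    df.insert(0, "trait", [f"trait{t + 1}" for t in range(p)])
    df["psi"] = truth.true_psi
    df["psi_h2"] = truth.true_psi_h2
    with open(path, "w") as fh:
        fh.write("# factor_h2\t" + "\t".join(map(str, truth.true_factor_h2)) + "\n")
        for o in truth.outlier_registry:
            fh.write(
                f"# outlier\tfactor={o.factor}\tline={o.line}\t"
                f"magnitude={o.magnitude}\tsign={o.sign}\n"
            )
        df.to_csv(fh, sep="\t", index=False)


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    data = {
        "n_lines": config.n_lines,
        "n_reps": config.n_reps,
        "n_traits": config.n_traits,
        "k_true": config.k_true,
        "factor_h2": list(config.factor_h2),
        "loading_density": config.loading_density,
        "loading_scale": config.loading_scale,
        "psi_range": list(config.psi_range),
        "psi_h2_range": list(config.psi_h2_range),
        "outliers": [
            {"factor": o.factor, "line": o.line, "magnitude": o.magnitude, "sign": o.sign}
            for o in config.outliers
        ],
        "tail_model": config.tail_model,
        "t_df": config.t_df,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    outliers = tuple(
        PlantedOutlier(
            factor=o["factor"], line=o["line"], magnitude=o["magnitude"],
            sign=o.get("sign", 1),
        )
        for o in data.pop("outliers", [])
    )
    for key in ("factor_h2", "psi_range", "psi_h2_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(outliers=outliers, **data)


def write_model_spec(spec: ModelSpec, path: str | Path) -> None:
    data = dict(spec.__dict__)
    data["h2_grid"] = [float(x) for x in data["h2_grid"]]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_model_spec(path: str | Path) -> ModelSpec:
    data = yaml.safe_load(Path(path).read_text())
    if "h2_grid" in data:
        data["h2_grid"] = tuple(data["h2_grid"])
    return ModelSpec(**data)


def write_posterior(samples: PosteriorSamples, path: str | Path) -> None:
    """Single HDF5 container keyed by parameter name; spec echoed as attrs."""
    with h5py.File(path, "w") as f:
        for name in (
            "Lambda", "F", "U_f", "h2_factors", "psi", "h2_specific", "B",
            "tau", "draw_iterations", "line_index",
        ):
            f.create_dataset(name, data=getattr(samples, name))
        if samples.spec is not None:
            for key, val in samples.spec.__dict__.items():
                f.attrs[key] = val if not isinstance(val, tuple) else list(val)


def read_posterior(path: str | Path) -> PosteriorSamples:
    with h5py.File(path, "r") as f:
        arrays = {
            name: f[name][()]
            for name in (
                "Lambda", "F", "U_f", "h2_factors", "psi", "h2_specific", "B",
                "tau", "draw_iterations", "line_index",
            )
        }
        spec = None
        if "k_max" in f.attrs:
            kwargs = dict(f.attrs)
            kwargs["h2_grid"] = tuple(float(x) for x in kwargs["h2_grid"])
            for key in ("k_max", "n_burn", "n_samples", "thin", "seed"):
                kwargs[key] = int(kwargs[key])
            for key in ("a1", "a2", "nu", "psi_shape", "psi_rate"):
                kwargs[key] = float(kwargs[key])
            spec = ModelSpec(**kwargs)
    return PosteriorSamples(spec=spec, **arrays)
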