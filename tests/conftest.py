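"""Shared fixtures: small synthetic panels and one reusable model fit."""

from __future__ import annotations

import numpy as np
import pytest

from bsfg import SimConfig, simulate_expression
from bsfg.model import ModelSpec, fit_bsfg
from bsfg.preprocess import scale_panel


@pytest.fixture(scope="session")
def strong_config() -> SimConfig:
    """Two well-separated heritable factors plus one planted outlier line."""
    from bsfg import PlantedOutlier

    return SimConfig(
        n_traits=60,
        k_true=2,
        factor_h2=(0.4, 0.9),
        loading_density=0.6,
        loading_scale=0.8,
        psi_range=(0.2, 0.5),
        outliers=(PlantedOutlier(factor=1, line=5, magnitude=6.0, sign=1),),
        seed=11,
    )


@pytest.fixture(scope="session")
def strong_panel(strong_config):
    panel, truth = simulate_expression(strong_config)
    return panel, truth


@pytest.fixture(scope="session")
def fitted(strong_panel):
    """One moderately long fit shared by model/inference/outlier tests."""
    panel, _truth = strong_panel
    scaled = scale_panel(panel, "sd")
    spec = ModelSpec(k_max=4, n_burn=600, n_samples=1200, thin=6, seed=7)
    samples = fit_bsfg(scaled, spec)
    return panel, scaled, samples


@pytest.fixture(scope="session")
def noise_panel():
    """A panel with no common factor structure (k_true = 0)."""
    cfg = SimConfig(n_traits=40, k_true=0, factor_h2=(), seed=23)
    panel, truth = simulate_expression(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def noise_fitted(noise_panel):
    panel, _ = noise_panel
    scaled = scale_panel(panel, "sd")
    spec = ModelSpec(k_max=4, n_burn=400, n_samples=800, thin=4, seed=3)
    return panel, scaled, fit_bsfg(scaled, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
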