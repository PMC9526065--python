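"""Sampler and covariance-reconstruction invariants."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

from bsfg import (
    ModelSpec,
    SimConfig,
    adjust_data,
    convergence_report,
    fit_bsfg,
    reconstruct_covariances,
    scale_panel,
    simulate_expression,
)
from bsfg.model import FactorModelState, PosteriorSamples


def _random_state(rng, p=15, k=3, n_lines=6):
    lam = rng.normal(size=(p, k))
    return FactorModelState(
        B=rng.normal(size=p),
        Lambda=lam,
        F=rng.normal(size=(2 * n_lines, k)),
        U_f=rng.normal(size=(n_lines, k)),
        h2_factors=rng.choice(np.linspace(0, 1, 21), size=k),
        psi=rng.uniform(0.2, 1.0, size=p),
        h2_specific=rng.choice(np.linspace(0, 1, 21), size=p),
        U_s=np.zeros((n_lines, p)),
        phi=np.ones((p, k)),
        delta=np.ones(k),
    )


def test_model_spec_validation():
    with pytest.raises(ValueError, match="a1 and a2"):
        ModelSpec(a1=0.5)
    with pytest.raises(ValueError, match="h2_grid"):
        ModelSpec(h2_grid=(0.0, 1.5))
    with pytest.raises(ValueError, match="contain 0"):
        ModelSpec(h2_grid=(0.1, 0.5, 1.0))
    with pytest.raises(ValueError, match="k_max"):
        ModelSpec(k_max=0)
    with pytest.raises(ValueError, match="chain"):
        ModelSpec(n_samples=0)


def test_k_max_bounded_by_samples():
    panel, _ = simulate_expression(SimConfig(n_traits=20, seed=0))
    scaled = scale_panel(panel, "sd")
    # 60 samples: k_max up to 59 is admissible, 60 is not
    with pytest.raises(ValueError, match="k_max=60"):
        fit_bsfg(scaled, ModelSpec(k_max=60, n_burn=1, n_samples=1))
    ModelSpec(k_max=59)  # constructing the admissible spec succeeds


def test_fit_requires_sd_scale(strong_panel):
    panel, _ = strong_panel
    with pytest.raises(ValueError, match="SD-scaled"):
        fit_bsfg(scale_panel(panel, "iqr"), ModelSpec(k_max=2, n_burn=1, n_samples=2))


def test_reconstruction_identity_and_psd(rng):
    for _ in range(5):
        state = _random_state(rng)
        G, R, P = reconstruct_covariances(state)
        direct = state.Lambda @ state.Lambda.T + np.diag(state.psi)
        assert np.allclose(G + R, P, atol=1e-12)
        assert np.allclose(P, direct, atol=1e-10)
        for M in (G, R, P):
            assert np.allclose(M, M.T, atol=1e-12)
            assert np.linalg.eigvalsh(M).min() > -1e-10


def test_reconstruction_h2_extremes(rng):
    state = _random_state(rng)
    state.h2_factors[:] = 0.0
    state.h2_specific[:] = 0.0
    G, R, P = reconstruct_covariances(state)
    assert np.allclose(G, 0.0, atol=1e-12)
    assert np.allclose(R, P, atol=1e-12)
    state.h2_factors[:] = 1.0
    state.h2_specific[:] = 1.0
    G, R, P = reconstruct_covariances(state)
    assert np.allclose(R, 0.0, atol=1e-12)
    assert np.allclose(G, P, atol=1e-12)


def test_reconstruction_invariant_to_column_sign_flip(rng):
    state = _random_state(rng)
    G0, R0, P0 = reconstruct_covariances(state)
    state.Lambda[:, 1] *= -1.0
    G1, R1, P1 = reconstruct_covariances(state)
    assert np.allclose(G0, G1, atol=1e-12)
    assert np.allclose(R0, R1, atol=1e-12)
    assert np.allclose(P0, P1, atol=1e-12)


def test_fit_output_shapes_and_ranges(fitted):
    panel, scaled, samples = fitted
    spec = samples.spec
    T = spec.n_samples // spec.thin
    n, p = scaled.values.shape
    assert samples.Lambda.shape == (T, p, spec.k_max)
    assert samples.F.shape == (T, n, spec.k_max)
    assert samples.U_f.shape == (T, panel.n_lines, spec.k_max)
    grid = np.asarray(spec.h2_grid)
    assert np.all(np.isin(samples.h2_factors, grid))
    assert np.all(np.isin(samples.h2_specific, grid))
    assert np.all(samples.psi > 0)
    assert np.all(samples.tau > 0)
    assert np.all(np.diff(samples.draw_iterations) == spec.thin)


def test_g_plus_r_equals_p_every_draw(fitted):
    _, _, samples = fitted
    for t in range(samples.n_draws):
        state = samples.state(t)
        G, R, P = reconstruct_covariances(state)
        assert np.max(np.abs(G + R - P)) < 1e-10


def test_fit_is_deterministic_given_seed(strong_panel):
    panel, _ = strong_panel
    scaled = scale_panel(panel, "sd")
    spec = ModelSpec(k_max=3, n_burn=50, n_samples=100, thin=5, seed=42)
    a = fit_bsfg(scaled, spec)
    b = fit_bsfg(scaled, spec)
    assert np.array_equal(a.Lambda, b.Lambda)
    assert np.array_equal(a.h2_factors, b.h2_factors)


def test_trailing_factors_shrink(fitted):
    """The multiplicative gamma process shrinks surplus columns."""
    _, _, samples = fitted
    col_var = (samples.Lambda**2).sum(axis=1).mean(axis=0)  # (k,)
    lead = np.sort(col_var)[::-1][:2].sum()
    assert col_var[-1] < 0.05 * lead


def test_strong_factors_recovered(fitted, strong_panel):
    """Posterior-mean loadings correlate with the planted ones."""
    _, truth = strong_panel
    _, scaled, samples = fitted
    truth_std = truth.true_loadings / scaled.scale[:, None]
    Lbar = samples.posterior_mean_Lambda()
    corr = np.abs(np.corrcoef(truth_std.T, Lbar.T)[:2, 2:])
    best = corr.max(axis=1)
    assert np.all(best > 0.85)


def test_pure_noise_panel_explains_little_variance():
    """On an iid-noise panel the common component FLambda' stays small."""
    cfg = SimConfig(n_traits=100, k_true=0, factor_h2=(),
                    psi_h2_range=(0.0, 0.0), seed=23)
    panel, _ = simulate_expression(cfg)
    scaled = scale_panel(panel, "sd")
    samples = fit_bsfg(
        scaled, ModelSpec(k_max=4, n_burn=400, n_samples=800, thin=4, seed=3)
    )
    total = scaled.values.var(axis=0, ddof=0).sum()
    fracs = [
        (samples.F[t] @ samples.Lambda[t].T).var(axis=0, ddof=0).sum() / total
        for t in range(samples.n_draws)
    ]
    assert np.mean(fracs) < 0.10


def test_adjust_data_zero_loadings_is_identity(fitted):
    _, scaled, samples = fitted
    import copy

    zeroed = copy.copy(samples)
    zeroed.Lambda = np.zeros_like(samples.Lambda)
    assert np.array_equal(adjust_data(scaled, zeroed), scaled.values)


def test_adjust_data_removes_common_signal(fitted):
    _, scaled, samples = fitted
    adjusted = adjust_data(scaled, samples)
    Lbar = samples.posterior_mean_Lambda()
    # traits with large communality lose most of their variance
    comm = (Lbar**2).sum(axis=1)
    heavy = comm > np.quantile(comm, 0.8)
    before = scaled.values[:, heavy].var(axis=0, ddof=1)
    after = adjusted[:, heavy].var(axis=0, ddof=1)
    assert np.median(after / before) < 0.5


def test_adjust_data_dimension_mismatch(fitted, noise_fitted):
    _, scaled, _ = fitted
    _, _, other = noise_fitted
    with pytest.raises(ValueError, match="dimensions"):
        adjust_data(scaled, other)


def _fake_samples(chains: np.ndarray) -> PosteriorSamples:
    T, q = chains.shape
    lam = chains.reshape(T, q, 1)
    k = 1
    return PosteriorSamples(
        Lambda=lam,
        F=np.zeros((T, 4, k)),
        U_f=np.zeros((T, 2, k)),
        h2_factors=np.zeros((T, k)),
        psi=np.ones((T, q)),
        h2_specific=np.zeros((T, q)),
        B=np.zeros((T, q)),
        tau=np.ones((T, k)),
        draw_iterations=np.arange(T),
        line_index=np.array([0, 0, 1, 1]),
    )


def test_convergence_report_iid_chains(rng):
    T, q = 500, 8000
    chains = rng.standard_normal((T, q))
    rep = convergence_report(_fake_samples(chains), lag=1, threshold=0.1)
    # iid chain lag-1 autocorrelation ~ N(0, 1/T)
    expected = 2 * norm.sf(0.1 * np.sqrt(T))
    assert rep.fraction_exceeding == pytest.approx(expected, abs=0.01)
    assert rep.n_flagged_constant == 0


def test_convergence_report_flags_sticky_and_constant_chains(rng):
    T = 400
    ar = np.empty(T)
    ar[0] = rng.standard_normal()
    for t in range(1, T):
        ar[t] = 0.8 * ar[t - 1] + rng.standard_normal()
    chains = np.column_stack([ar, np.full(T, 2.5)])
    rep = convergence_report(_fake_samples(chains))
    assert rep.fraction_exceeding == 1.0  # the AR chain, constants excluded
    assert rep.n_flagged_constant == 1


def test_convergence_report_needs_draws(rng):
    with pytest.raises(ValueError, match="at least 10"):
        convergence_report(_fake_samples(rng.standard_normal((5, 3))))
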