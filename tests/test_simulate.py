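"""Generator invariants: determinism, structure, variance accounting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from bsfg import PlantedOutlier, SimConfig, simulate_expression, simulate_normal_reference


def test_default_config_matches_study_design():
    cfg = SimConfig()
    assert cfg.n_lines == 30
    assert cfg.n_reps == 2
    assert cfg.n_traits == 3385
    panel, _ = simulate_expression(SimConfig(n_traits=50))
    assert panel.values.shape == (60, 50)
    assert panel.n_lines == 30
    assert panel.reps_per_line == 2


def test_same_seed_is_bit_identical():
    cfg = SimConfig(n_traits=40, seed=5)
    p1, t1 = simulate_expression(cfg)
    p2, t2 = simulate_expression(cfg)
    assert np.array_equal(p1.values, p2.values)
    assert np.array_equal(t1.true_loadings, t2.true_loadings)
    assert np.array_equal(t1.true_sample_values, t2.true_sample_values)


def test_different_seeds_differ():
    a, _ = simulate_expression(SimConfig(n_traits=40, seed=1))
    b, _ = simulate_expression(SimConfig(n_traits=40, seed=2))
    assert not np.array_equal(a.values, b.values)


def test_ground_truth_shapes_and_consistency():
    cfg = SimConfig(n_traits=25, k_true=2, factor_h2=(0.2, 0.7), seed=3)
    panel, truth = simulate_expression(cfg)
    assert truth.true_loadings.shape == (25, 2)
    assert truth.true_line_values.shape == (30, 2)
    assert truth.true_sample_values.shape == (60, 2)
    assert truth.true_psi.shape == (25,)
    # sample values = line value + replicate deviation, grouped by line
    li = panel.line_index
    dev = truth.true_sample_values - truth.true_line_values[li]
    assert np.all(np.isfinite(dev))
    lo, hi = cfg.psi_range
    assert np.all((truth.true_psi >= lo) & (truth.true_psi <= hi))


def test_no_factors_means_independent_traits():
    """With k_true=0 the traits share nothing but line-specific noise."""
    big, _ = simulate_expression(
        SimConfig(n_lines=400, n_traits=10, k_true=0, factor_h2=(),
                  psi_h2_range=(0.0, 0.0), seed=9)
    )
    small, _ = simulate_expression(
        SimConfig(n_lines=40, n_traits=10, k_true=0, factor_h2=(),
                  psi_h2_range=(0.0, 0.0), seed=9)
    )

    def mean_abs_offdiag(values):
        c = np.corrcoef(values.T)
        return np.abs(c[np.triu_indices_from(c, 1)]).mean()

    assert mean_abs_offdiag(big.values) < 0.05
    assert mean_abs_offdiag(big.values) < mean_abs_offdiag(small.values)


def test_between_line_variance_matches_h2():
    """Across many panels the line values realize the planted heritability."""
    h2 = 0.6
    n_panels = 500
    vs = []
    for seed in range(n_panels):
        _, truth = simulate_expression(
            SimConfig(n_traits=3, k_true=1, factor_h2=(h2,), seed=seed)
        )
        vs.append(truth.true_line_values[:, 0].var(ddof=1))
    # sample variance of 30 iid N(0, h2) values: SE of the mean over panels
    se = h2 * np.sqrt(2.0 / 29.0) / np.sqrt(n_panels)
    assert abs(np.mean(vs) - h2) < 3 * se


def test_marginal_trait_variance_accounting():
    """Marginal variance ~ sum of squared loadings + psi for normal tails."""
    cfg = SimConfig(n_lines=500, n_traits=12, k_true=2, factor_h2=(0.4, 0.8),
                    loading_density=1.0, loading_scale=0.5, seed=17)
    panel, truth = simulate_expression(cfg)
    expected = (truth.true_loadings**2).sum(axis=1) + truth.true_psi
    observed = panel.values.var(axis=0, ddof=1)
    assert np.allclose(observed, expected, rtol=0.25)


def test_planted_outlier_shifts_line_value():
    out = PlantedOutlier(factor=0, line=4, magnitude=6.0, sign=-1)
    cfg = SimConfig(n_traits=10, k_true=1, factor_h2=(0.8,), outliers=(out,), seed=2)
    base = SimConfig(n_traits=10, k_true=1, factor_h2=(0.8,), seed=2)
    _, with_out = simulate_expression(cfg)
    _, without = simulate_expression(base)
    diff = with_out.true_line_values - without.true_line_values
    assert diff[4, 0] == pytest.approx(-6.0)
    diff[4, 0] = 0.0
    assert np.allclose(diff, 0.0)


def test_planted_outlier_line_is_recoverably_extreme():
    """A 6-latent-SD shift at h2=0.9 dwarfs the line-value IQR ~95% of runs."""
    hits = 0
    n_runs = 200
    for seed in range(n_runs):
        rng = np.random.default_rng(seed)
        line = int(rng.integers(0, 30))
        cfg = SimConfig(
            n_traits=3, k_true=1, factor_h2=(0.9,),
            outliers=(PlantedOutlier(factor=0, line=line, magnitude=6.0),),
            seed=seed,
        )
        _, truth = simulate_expression(cfg)
        u = truth.true_line_values[:, 0]
        q75, q25 = np.percentile(u, [75, 25])
        iqr = q75 - q25
        hits += int(u[line] - np.median(u) > 3 * iqr)
    assert hits / n_runs >= 0.95


def test_t_tails_are_heavier():
    normal, _ = simulate_expression(
        SimConfig(n_lines=400, n_traits=20, k_true=0, factor_h2=(),
                  tail_model="normal", seed=6)
    )
    heavy, _ = simulate_expression(
        SimConfig(n_lines=400, n_traits=20, k_true=0, factor_h2=(),
                  tail_model="t", t_df=3.0, seed=6)
    )
    kn = stats.kurtosis(normal.values, axis=None)
    kt = stats.kurtosis(heavy.values, axis=None)
    assert kt > kn + 0.5


@pytest.mark.parametrize(
    "kwargs, fragment",
    [
        (dict(n_traits=0), "n_lines, n_reps and n_traits"),
        (dict(k_true=1, factor_h2=()), "factor_h2"),
        (dict(k_true=1, factor_h2=(1.5,)), "factor_h2"),
        (dict(loading_density=0.0), "loading_density"),
        (dict(loading_scale=-1.0), "loading_scale"),
        (dict(psi_range=(0.0, 1.0)), "psi_range"),
        (dict(psi_h2_range=(0.2, 1.2)), "psi_h2_range"),
        (dict(tail_model="cauchy"), "tail_model"),
        (dict(tail_model="t", t_df=2.0), "t_df"),
        (
            dict(k_true=1, factor_h2=(0.5,),
                 outliers=(PlantedOutlier(factor=3, line=0, magnitude=2.0),)),
            "factor index",
        ),
        (
            dict(k_true=1, factor_h2=(0.5,),
                 outliers=(PlantedOutlier(factor=0, line=99, magnitude=2.0),)),
            "line index",
        ),
    ],
)
def test_invalid_configs_name_the_field(kwargs, fragment):
    with pytest.raises(ValueError, match=fragment):
        SimConfig(**kwargs)


def test_invalid_planted_outlier():
    with pytest.raises(ValueError, match="magnitude"):
        PlantedOutlier(factor=0, line=0, magnitude=0.0)
    with pytest.raises(ValueError, match="sign"):
        PlantedOutlier(factor=0, line=0, magnitude=1.0, sign=2)


def test_normal_reference_is_deterministic_and_standard():
    a = simulate_normal_reference(5, 200_000, seed=1)
    b = simulate_normal_reference(5, 200_000, seed=1)
    assert np.array_equal(a, b)
    assert a.shape == (200_000, 5)
    pooled = a.ravel()
    assert abs(pooled.mean()) < 0.005
    q75, q25 = np.percentile(pooled, [75, 25])
    # normal IQR = 2 * 0.674490 sigma = 1.349
    assert q75 - q25 == pytest.approx(1.349, abs=0.01)


def test_panel_line_rep_array_round_trip():
    panel, _ = simulate_expression(SimConfig(n_traits=8, seed=4))
    arr = panel.line_rep_array()
    assert arr.shape == (30, 2, 8)
    li = panel.line_index
    for i in (0, 13, 29):
        rows = panel.values[li == i]
        assert np.allclose(np.sort(arr[i], axis=0), np.sort(rows, axis=0))


def test_panel_rejects_duplicate_and_unbalanced_labels():
    from bsfg import ExpressionPanel

    values = np.zeros((4, 2))
    with pytest.raises(ValueError, match="duplicated"):
        ExpressionPanel(
            values=values,
            sample_line=np.array(["a", "a", "b", "b"]),
            sample_rep=np.array(["1", "1", "1", "2"]),
            trait_ids=np.array(["t1", "t2"]),
        )
    with pytest.raises(ValueError, match="same replicate count"):
        ExpressionPanel(
            values=np.zeros((3, 2)),
            sample_line=np.array(["a", "a", "b"]),
            sample_rep=np.array(["1", "2", "1"]),
            trait_ids=np.array(["t1", "t2"]),
        )
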