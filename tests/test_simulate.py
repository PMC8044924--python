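"""Synthetic experiment generator: food series, ODE truth, counting noise."""

import warnings

import numpy as np
import pytest

from nrfr import (
    ExperimentDesign,
    FunctionalResponse,
    GeneratingModel,
    NumericalResponse,
    food_series,
    parameter_recovery_suite,
    rates_table,
    simulate_experiment,
    simulate_well,
)


def test_food_series_constant_factor_spans_range_exactly():
    design = ExperimentDesign(geometric_factor=1.221)
    levels = food_series(design)
    assert levels[0] == pytest.approx(1e3)
    assert levels[-1] == 1e5
    ratios = levels[1:] / levels[:-1]
    assert np.allclose(ratios, ratios[0])  # constant factor preserved by rescaling


def test_food_series_two_wells_is_min_max():
    levels = food_series(ExperimentDesign(n_wells=2, geometric_factor=1.2))
    assert levels == pytest.approx([1e3, 1e5])


def test_food_series_random_factors_deterministic_and_monotone():
    design = ExperimentDesign()
    a = food_series(design, np.random.default_rng(3))
    b = food_series(design, np.random.default_rng(3))
    assert np.array_equal(a, b)
    assert np.all(np.diff(a) > 0)
    assert a[0] == pytest.approx(1e3) and a[-1] == 1e5


def test_invalid_designs_rejected():
    with pytest.raises(ValueError):
        ExperimentDesign(prey_min=10, prey_max=5)
    with pytest.raises(ValueError):
        ExperimentDesign(factor_range=(0.9, 1.5))
    with pytest.raises(ValueError):
        GeneratingModel(nr=(0.4, 0.1, 0.2))  # no functional response given


def test_decoupled_limit_matches_exponential_closed_form():
    """Zero ingestion and a flat growth response reduce every population to
    independent exponentials."""
    mu0 = 0.35
    gm = GeneratingModel(nr=(mu0, 0.0, 1e-12), fr_slope=0.0, prey_growth_rate=0.25)
    design = ExperimentDesign()
    obs, truth = simulate_well(5e4, gm, design, noiseless=True)
    t = design.duration_d
    assert obs.nt == pytest.approx(20 * np.exp(mu0 * t), rel=1e-6)
    assert obs.pt == pytest.approx(5e4 * np.exp(0.25 * t), rel=1e-6)
    assert obs.ct == pytest.approx(5e4 * np.exp(0.25 * t), rel=1e-6)


def test_linear_grazing_scalar_ode_closed_form():
    """With non-growing prey, negligible predator growth and a linear FR of
    slope s, prey decays as exp(-s*R0*t/1000) (per-ml carbon bookkeeping)."""
    s = 2.5  # ng C/cell/d per mg C/liter
    gm = GeneratingModel(
        nr=(1e-9, 0.0, 1.0), fr_slope=s, prey_growth_rate=0.0, prey_cell_carbon_pg=34.0
    )
    design = ExperimentDesign(initial_predators=20.0)
    obs, truth = simulate_well(5e4, gm, design, noiseless=True)
    expected = 5e4 * np.exp(-s * 20.0 / 1000.0 * design.duration_d)
    assert obs.pt == pytest.approx(expected, rel=1e-6)


def test_simulation_determinism_bit_identical(vnatans_model):
    a = simulate_experiment(vnatans_model, seed=17).to_frame()
    b = simulate_experiment(vnatans_model, seed=17).to_frame()
    assert a.equals(b)
    c = simulate_experiment(vnatans_model, seed=18).to_frame()
    assert not a.equals(c)


def test_no_negative_abundances(noisy_plate):
    df = noisy_plate.to_frame()
    assert (df["count_per_ml"] >= 0).all()
    for truth in noisy_plate.truth:
        assert truth["prey_end_cells_ml"] >= 0 and truth["predators_end_per_ml"] >= 0


def test_prey_carbon_mass_balance(noiseless_plate):
    """Prey produced must equal prey remaining plus prey consumed: the true
    endpoint never exceeds pure exponential growth of the inoculum."""
    mu_prey = noiseless_plate.generating_model.prey_mu(15.0)
    t = noiseless_plate.design.duration_d
    for truth in noiseless_plate.truth:
        ceiling = truth["level_cells_ml"] * np.exp(mu_prey * t)
        assert truth["prey_end_cells_ml"] <= ceiling * (1 + 1e-7)


def test_noiseless_pipeline_recovers_generating_parameters(vnatans_model, noiseless_plate):
    """Endpoint formulas applied to exact ODE endpoints recover the NR truth
    to within the endpoint-estimator's structural bias (< 2% on mu_max)."""
    rates = rates_table(noiseless_plate.wells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nr = NumericalResponse.from_rates(rates).fit()
        fr = FunctionalResponse.from_rates(rates).fit()
    assert nr.mu_max == pytest.approx(0.45, rel=0.02)
    assert nr.p_prime == pytest.approx(0.10, abs=0.01)
    assert nr.k2 == pytest.approx(0.18, rel=0.10)
    assert fr.selected == "holling_II"
    assert fr.i_max == pytest.approx(28.54, rel=0.05)


def test_counting_noise_vanishes_with_large_counting_volumes(vnatans_model):
    """As counted volumes grow the noisy estimates collapse onto the
    noiseless ones."""
    big = ExperimentDesign(
        ciliate_count_volume_ml=2000.0,
        prey_count_target=2_000_000,
        prey_count_volume_ml=(1e-3, 5e3),
    )
    noisy = simulate_experiment(vnatans_model, big, seed=4)
    exact = simulate_experiment(vnatans_model, big, seed=4, noiseless=True)
    for w_noisy, w_exact in zip(noisy.wells, exact.wells):
        assert w_noisy.nt == pytest.approx(w_exact.nt, rel=0.05)
        assert w_noisy.pt == pytest.approx(w_exact.pt, rel=0.01)


def test_recovery_suite_near_zero_bias_without_noise(vnatans_model):
    """Huge counting volumes: residual bias is bounded by the endpoint/ODE
    structural bias, not by sampling noise."""
    big = ExperimentDesign(ciliate_count_volume_ml=5000.0, prey_count_target=5_000_000)
    rep = parameter_recovery_suite(vnatans_model, big, n_replicates=10, seed=6)
    assert abs(rep["parameters"]["mu_max"]["bias"]) < 0.01
    assert abs(rep["parameters"]["p_prime"]["bias"]) < 0.01
    assert rep["n_failed"] == 0


def test_zero_threshold_truth_respects_boundary():
    gm = GeneratingModel(nr=(0.45, 0.0, 0.18), fr_holling=(28.54, 4.09))
    rep = parameter_recovery_suite(gm, n_replicates=30, seed=8)
    est = rep["estimates"]["p_prime_hat"]
    assert (est >= 0).all()  # bound respected, no negative thresholds
    assert est.median() < 0.05  # distribution concentrates near the boundary


def test_well_level_outside_design_rejected(vnatans_model):
    with pytest.raises(ValueError):
        simulate_well(10.0, vnatans_model, ExperimentDesign(), noiseless=True)
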