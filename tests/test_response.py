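"""Numerical/functional response fitting, evaluation, and GGE."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrfr import (
    FitError,
    FunctionalResponse,
    NumericalResponse,
    evaluate_fr,
    evaluate_nr,
    gross_growth_efficiency,
    initial_slope,
)

PAPER_GRID = np.geomspace(0.02, 7.0, 24)  # mg C/liter food series used throughout


def _fit_nr(mu, p):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return NumericalResponse(mu, p).fit()


# ---------------------------------------------------------------------------
# evaluation


def test_nr_zero_at_threshold_and_saturates():
    params = (0.45, 0.10, 0.18)
    assert evaluate_nr(params, 0.10) == pytest.approx(0.0)
    p = np.linspace(0.11, 50, 500)
    mu = evaluate_nr(params, p)
    assert np.all(np.diff(mu) > 0)  # strictly increasing above threshold
    assert evaluate_nr(params, 1e6) == pytest.approx(0.45, rel=1e-4)
    assert evaluate_nr(params, 0.05) < 0  # below threshold: negative model value


def test_fr_half_saturation_identity():
    """Holling II returns exactly I_max/2 at P = k."""
    imax, k = 28.54, 4.09
    assert evaluate_fr((imax, k), k) == pytest.approx(imax / 2)
    assert evaluate_fr((imax, k), 0.0) == 0.0
    p = np.linspace(0.01, 30, 300)
    i = evaluate_fr((imax, k), p)
    assert np.all(np.diff(i) > 0) and np.all(np.diff(i, 2) < 0)  # increasing, concave


@pytest.mark.parametrize(
    "mu_max,k2,expected",
    [(0.38, 0.93, 0.41), (0.36, 0.61, 0.59), (1.0, 1.0, 1.0)],
)
def test_initial_slope(mu_max, k2, expected):
    assert initial_slope(mu_max, k2) == pytest.approx(expected, abs=0.005)


def test_initial_slope_delta_se_matches_monte_carlo(rng):
    """In the small-noise regime where the first-order delta method is exact,
    its SE matches a Monte-Carlo ratio distribution."""
    cov = np.array([[0.005**2, 0.0], [0.0, 0.02**2]])
    alpha, se = initial_slope(0.38, 0.93, cov)
    draws = rng.multivariate_normal([0.38, 0.93], cov, size=200_000)
    mc = np.std(draws[:, 0] / draws[:, 1])
    assert se == pytest.approx(mc, rel=0.05)


# ---------------------------------------------------------------------------
# numerical-response fitting


def test_noiseless_nr_recovery_to_six_digits():
    truth = (0.45, 0.10, 0.18)
    res = _fit_nr(evaluate_nr(truth, PAPER_GRID), PAPER_GRID)
    assert res.params == pytest.approx(truth, rel=1e-6)
    assert res.alpha == pytest.approx(0.45 / 0.18, rel=1e-6)
    assert res.converged


def test_nr_optimizer_beats_grid_search_oracle(rng):
    """On one noisy dataset the optimizer's RSS is at least as good as a
    brute-force grid over (mu_max, P', k2)."""
    truth = (0.45, 0.10, 0.18)
    mu = evaluate_nr(truth, PAPER_GRID) + rng.normal(0, 0.03, PAPER_GRID.size)
    res = _fit_nr(mu, PAPER_GRID)

    def rss(theta):
        return float(np.sum((evaluate_nr(theta, PAPER_GRID) - mu) ** 2))

    grid = itertools.product(
        np.linspace(0.3, 0.6, 25), np.linspace(0.0, 0.3, 25), np.linspace(0.05, 0.5, 25)
    )
    best_grid = min(rss(theta) for theta in grid)
    assert res.rss <= best_grid + 1e-12


def test_noisy_nr_median_estimates_near_truth():
    """Gaussian noise sigma=0.03 on the experiment's food grid: the median of
    replicate estimates stays within one median SE of the truth."""
    truth = np.array([0.45, 0.10, 0.18])
    rng = np.random.default_rng(42)
    est, ses = [], []
    for _ in range(150):
        mu = evaluate_nr(truth, PAPER_GRID) + rng.normal(0, 0.03, PAPER_GRID.size)
        res = _fit_nr(mu, PAPER_GRID)
        est.append(res.params)
        ses.append(res.bse)
    med = np.median(est, axis=0)
    med_se = np.median(ses, axis=0)
    assert np.all(np.abs(med - truth) <= med_se)


def test_flat_response_flagged_non_identifiable():
    mu = np.full(PAPER_GRID.size, 0.3)
    res = _fit_nr(mu, PAPER_GRID)
    assert not res.converged or "non_identifiable" in res.flags or "at_bound" in res.flags


def test_nr_input_validation():
    with pytest.raises(FitError):
        NumericalResponse([-0.1, -0.2, -0.3, -0.05, -0.4, -0.1], PAPER_GRID[:6])
    with pytest.raises(FitError):
        NumericalResponse([0.1, 0.2, 0.3], [0.1, 0.5, 1.0])


def test_nr_conf_band_contains_fit_and_widens():
    truth = (0.45, 0.10, 0.18)
    rng = np.random.default_rng(5)
    mu = evaluate_nr(truth, PAPER_GRID) + rng.normal(0, 0.03, PAPER_GRID.size)
    res = _fit_nr(mu, PAPER_GRID)
    grid = np.linspace(0.05, 7, 50)
    lo, hi = res.conf_band(grid)
    fit = res.predict(grid)
    assert np.all(lo <= fit) and np.all(fit <= hi)
    blo, bhi = res.conf_band(grid, method="bootstrap", n_boot=400, seed=1)
    # the two band constructions agree to the order of the band width
    assert np.median(bhi - blo) == pytest.approx(np.median(hi - lo), rel=0.5)


def test_nr_summary_mentions_all_parameters():
    res = _fit_nr(evaluate_nr((0.45, 0.1, 0.18), PAPER_GRID), PAPER_GRID)
    text = res.summary()
    for token in ("mu_max", "p_prime", "k2", "alpha"):
        assert token in text


# ---------------------------------------------------------------------------
# functional-response fitting


def test_noiseless_holling_recovery_and_selection():
    truth = (4.94, 0.52)
    res = FunctionalResponse(evaluate_fr(truth, PAPER_GRID), PAPER_GRID).fit()
    assert res.selected == "holling_II"
    assert res.holling["params"] == pytest.approx(truth, rel=1e-6)
    assert not res.holling_divergent


def test_linear_data_selects_linear_and_flags_divergence():
    res = FunctionalResponse(3.0 * PAPER_GRID, PAPER_GRID).fit()
    assert res.selected == "linear"
    assert res.holling_divergent  # Holling ran to its bound: unsaturated
    assert res.slope == pytest.approx(3.0, rel=1e-9)


def test_noisy_holling_selected_when_saturation_in_range():
    """Holling-II data with 10% noise and k at ~7% of the P-range: the
    saturating model should win model selection in most replicates."""
    truth = (4.94, 0.52)
    rng = np.random.default_rng(7)
    wins = 0
    n_rep = 200
    for _ in range(n_rep):
        i_true = evaluate_fr(truth, PAPER_GRID)
        i_obs = np.clip(i_true + rng.normal(0, 0.1 * i_true), 0, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = FunctionalResponse(i_obs, PAPER_GRID).fit()
        wins += res.selected == "holling_II"
    assert wins / n_rep > 0.8


def test_holling_never_beats_line_on_linear_data_beyond_noise_floor():
    """Model-selection sanity on truly linear data: the Holling fit's AICc
    advantage is bounded by the one-extra-parameter chance improvement (a
    chi-square(1) fluctuation), i.e. the typical advantage is negative and
    spurious saturating verdicts stay at the AICc false-positive rate."""
    rng = np.random.default_rng(99)
    deltas, holling_wins = [], 0
    n_rep = 200
    for _ in range(n_rep):
        i_obs = np.clip(3.0 * PAPER_GRID + rng.normal(0, 0.3, PAPER_GRID.size), 0, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = FunctionalResponse(i_obs, PAPER_GRID).fit()
        holling_wins += res.selected == "holling_II"
        if res.holling is not None and np.isfinite(res.holling["aicc"]):
            delta = res.holling["aicc"] - res.linear["aicc"]
            # noise floor: penalty gap minus the largest plausible chi2(1)
            # draw across n_rep replicates (~2*log(n_rep) + tail margin)
            assert delta > -(2 * np.log(n_rep) + 5)
            deltas.append(delta)
    assert np.median(deltas) > 0  # line preferred in the typical replicate
    assert holling_wins / n_rep < 0.15  # at most the AICc chance rate


def test_fr_input_validation():
    with pytest.raises(FitError):
        FunctionalResponse([1.0, -0.5, 2.0, 3.0, 4.0, 5.0], PAPER_GRID[:6])
    with pytest.raises(FitError):
        FunctionalResponse([1.0, 2.0], [0.1, 0.2])


# ---------------------------------------------------------------------------
# gross growth efficiency


def test_gge_worked_examples():
    res = gross_growth_efficiency(0.31, 3.4, 2.8, food_level_mg_l=0.5, temperature_c=15)
    assert res.gge == pytest.approx(0.376, abs=0.005)
    assert res.percent > 30  # efficient growth at moderate temperature
    low = gross_growth_efficiency(0.13, 2.6, 3.9, temperature_c=10)
    assert low.gge == pytest.approx(0.091, abs=0.01)  # printed 9.1%, input rounding
    assert gross_growth_efficiency(0.0, 3.4, 2.8).gge == 0.0


def test_gge_guard_rails():
    with pytest.raises(FitError):
        gross_growth_efficiency(0.3, 3.4, 0.0)
    with pytest.warns(UserWarning):
        gross_growth_efficiency(2.0, 3.4, 1.0)  # fraction > 1 is suspect, not fatal
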