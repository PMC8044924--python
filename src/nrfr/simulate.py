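"""Synthetic microcosm grazing experiments with known ground truth.

Emulates the standard 24-well endpoint design for protist numerical/
functional response work: a geometric progression of initial prey levels
spanning two orders of magnitude (1e3-1e5 cells/ml by default, step
factor 1.1-1.5), a fixed predator inoculum (20 cells/ml), a 48-h
incubation, a predator-free control per food level, and endpoint counts
with Poisson counting noise (the whole 1-ml predator subsample counted,
~10-50 cells; prey subsampled to a target of a few hundred counted
cells).

Within a well, prey and predator follow the coupled batch dynamics

    dA/dt = mu_prey*A - (I(P)/m) * R        (prey cells/ml)
    dR/dt = mu(P) * R                       (predators/ml)

with P the prey biomass in mg C/liter, m the prey per-cell carbon, mu(P)
the threshold numerical response and I(P) the functional response.  The
endpoint estimators assume piecewise-exponential change, so a small,
quantifiable systematic bias relative to this ODE truth is expected —
the recovery suite measures it instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .rates import WellObservation, rates_table
from .response import NumericalResponse, evaluate_fr, evaluate_nr

__all__ = [
    "ExperimentDesign",
    "GeneratingModel",
    "SyntheticExperiment",
    "food_series",
    "simulate_well",
    "simulate_experiment",
    "parameter_recovery_suite",
]

#: default control prey growth rates (d^-1) by incubation temperature (°C);
#: free parameters of the generator, chosen as plausible batch-culture rates
#: for a cryptophyte rising with temperature.
DEFAULT_PREY_GROWTH = {5.0: 0.10, 10.0: 0.20, 15.0: 0.30, 18.0: 0.35, 20.0: 0.40}


@dataclass(frozen=True)
class ExperimentDesign:
    """Geometry and counting protocol of one simulated plate."""

    n_wells: int = 24
    prey_min: float = 1e3  # cells/ml
    prey_max: float = 1e5  # cells/ml
    factor_range: Tuple[float, float] = (1.1, 1.5)
    geometric_factor: Optional[float] = None  # fixed step factor; None -> random per step
    duration_d: float = 2.0
    initial_predators: float = 20.0  # cells/ml
    temperature_c: float = 15.0
    ciliate_count_volume_ml: float = 1.0
    prey_count_target: int = 400  # counted cells aimed for (200-600 typical)
    prey_count_volume_ml: Tuple[float, float] = (1e-3, 1.0)  # subsample bounds

    def __post_init__(self) -> None:
        if self.n_wells < 2:
            raise ValueError("need at least 2 wells")
        if not (0 < self.prey_min < self.prey_max):
            raise ValueError("prey range must satisfy 0 < min < max")
        lo, hi = self.factor_range
        if not (1.0 < lo <= hi):
            raise ValueError("factor range must be > 1 and ordered")
        if self.geometric_factor is not None and self.geometric_factor <= 1.0:
            raise ValueError("geometric factor must exceed 1")
        if self.duration_d <= 0 or self.initial_predators <= 0:
            raise ValueError("duration and inoculum must be positive")


@dataclass(frozen=True)
class GeneratingModel:
    """Ground-truth response curves driving a simulated experiment.

    ``nr`` is (mu_max d^-1, P' mg C/L, k2 mg C/L); the functional
    response is Holling II when ``fr_holling`` = (I_max ng C/cell/d,
    k mg C/L) is given, otherwise linear with ``fr_slope``.
    """

    nr: Tuple[float, float, float]
    fr_holling: Optional[Tuple[float, float]] = None
    fr_slope: Optional[float] = None
    prey_growth_rate: Optional[float] = None  # d^-1; None -> temperature default
    prey_cell_carbon_pg: float = 34.0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if (self.fr_holling is None) == (self.fr_slope is None):
            raise ValueError("specify exactly one of fr_holling or fr_slope")
        if not all(np.isfinite(self.nr)):
            raise ValueError("NR parameters must be finite")

    def ingestion(self, p_mg_l):
        if self.fr_holling is not None:
            return evaluate_fr(self.fr_holling, p_mg_l)
        return evaluate_fr(self.fr_slope, p_mg_l)

    def growth(self, p_mg_l):
        return evaluate_nr(self.nr, p_mg_l)

    def prey_mu(self, temperature_c: float) -> float:
        if self.prey_growth_rate is not None:
            return self.prey_growth_rate
        key = min(DEFAULT_PREY_GROWTH, key=lambda t: abs(t - temperature_c))
        return DEFAULT_PREY_GROWTH[key]


def food_series(design: ExperimentDesign, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Initial prey levels (cells/ml), geometric progression spanning the range.

    Per-step factors are drawn uniformly from the design's factor range
    (or fixed by ``geometric_factor``), then rescaled in log space so the
    first level equals the minimum and the last exactly the maximum.
    """
    n = design.n_wells
    if design.geometric_factor is not None:
        incr = np.full(n - 1, np.log(design.geometric_factor))
    else:
        if rng is None:
            raise ValueError("random factors need an rng; pass one or fix geometric_factor")
        lo, hi = design.factor_range
        incr = np.log(rng.uniform(lo, hi, size=n - 1))
    total = np.log(design.prey_max / design.prey_min)
    incr = incr * (total / incr.sum())
    levels = design.prey_min * np.exp(np.concatenate([[0.0], np.cumsum(incr)]))
    levels[-1] = design.prey_max  # exact despite rounding
    return levels


def _count(true_density: float, volume_ml: float, rng) -> float:
    """Poisson-count ``true_density`` cells/ml in a ``volume_ml`` subsample.

    Returns the density estimate count/volume; a zero count is kept as 0
    (extinction is a legitimate observation) except at t0 where callers
    re-draw.
    """
    return rng.poisson(true_density * volume_ml) / volume_ml


def _count_positive(true_density: float, volume_ml: float, rng) -> float:
    est = _count(true_density, volume_ml, rng)
    while est == 0:  # initial inocula are verified non-empty before a run starts
        est = _count(true_density, volume_ml, rng)
    return est


def _prey_volume(design: ExperimentDesign, density: float) -> float:
    lo, hi = design.prey_count_volume_ml
    return float(np.clip(design.prey_count_target / max(density, 1e-9), lo, hi))


def simulate_well(
    level: float,
    gm: GeneratingModel,
    design: ExperimentDesign,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "w0",
    noiseless: bool = False,
) -> Tuple[WellObservation, dict]:
    """Integrate one treatment well plus its paired control.

    Returns the (noisy or exact) endpoint ``WellObservation`` and a truth
    dict holding the latent trajectories' endpoints and the generating
    rates at this food level.
    """
    if not (design.prey_min * 0.999 <= level <= design.prey_max * 1.001):
        raise ValueError(f"prey level {level} outside design range")
    m_ng = gm.prey_cell_carbon_pg / 1000.0  # ng C per prey cell
    mu_prey = gm.prey_mu(design.temperature_c)
    t = design.duration_d

    def rhs(_t, y):
        a, r = max(y[0], 0.0), max(y[1], 0.0)
        p_mg_l = a * m_ng / 1000.0
        ing = gm.ingestion(p_mg_l)  # ng C/cell/d
        da = mu_prey * a - ing / m_ng * r
        dr = gm.growth(p_mg_l) * r
        return (da, dr)

    sol = solve_ivp(
        rhs,
        (0.0, t),
        (level, design.initial_predators),
        method="LSODA",
        rtol=1e-8,
        atol=(1e-6, 1e-9),
    )
    if not sol.success:
        raise RuntimeError(f"well {well_id}: integration failed: {sol.message}")
    a_t = max(float(sol.y[0, -1]), 0.0)
    r_t = max(float(sol.y[1, -1]), 0.0)
    c_t = level * np.exp(mu_prey * t)  # predator-free control, closed form

    truth = {
        "level_cells_ml": level,
        "prey_end_cells_ml": a_t,
        "predators_end_per_ml": r_t,
        "control_end_cells_ml": c_t,
        "mu_prey": mu_prey,
        "p0_mg_l": level * m_ng / 1000.0,
    }

    if noiseless:
        n0, nt = design.initial_predators, r_t
        p0, pt, c0, ct = level, a_t, level, c_t
    else:
        if rng is None:
            raise ValueError("noisy simulation needs an rng")
        v_cil = design.ciliate_count_volume_ml
        n0 = _count_positive(design.initial_predators, v_cil, rng)
        nt = _count(r_t, v_cil, rng)
        p0 = _count_positive(level, _prey_volume(design, level), rng)
        pt = _count(a_t, _prey_volume(design, a_t), rng)
        c0 = _count_positive(level, _prey_volume(design, level), rng)
        ct = _count(c_t, _prey_volume(design, c_t), rng)

    obs = WellObservation(
        well_id=well_id,
        species=gm.species,
        temperature_c=design.temperature_c,
        n0=n0,
        nt=nt,
        p0=p0,
        pt=pt,
        c0=c0,
        ct=ct,
        duration_d=t,
        prey_cell_carbon_pg=gm.prey_cell_carbon_pg,
    )
    return obs, truth


@dataclass
class SyntheticExperiment:
    """One simulated plate: wells, per-well truth, and its provenance."""

    design: ExperimentDesign
    generating_model: GeneratingModel
    seed: int
    wells: list = field(default_factory=list)
    truth: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy plate table in the pipeline input schema."""
        rows = []
        for w in self.wells:
            common = dict(
                well_id=w.well_id,
                species=w.species,
                temperature_C=w.temperature_c,
                duration_d=w.duration_d,
                prey_cell_carbon_pg=w.prey_cell_carbon_pg,
            )
            for role, org, tp, val in [
                ("treatment", "predator", "t0", w.n0),
                ("treatment", "predator", "t2", w.nt),
                ("treatment", "prey", "t0", w.p0),
                ("treatment", "prey", "t2", w.pt),
                ("control", "prey", "t0", w.c0),
                ("control", "prey", "t2", w.ct),
            ]:
                rows.append({**common, "role": role, "organism": org, "timepoint": tp, "count_per_ml": val})
        return pd.DataFrame(rows)

    def truth_record(self) -> dict:
        gm = self.generating_model
        return {
            "seed": self.seed,
            "nr": {"mu_max": gm.nr[0], "p_prime": gm.nr[1], "k2": gm.nr[2]},
            "fr": (
                {"model": "holling_II", "i_max": gm.fr_holling[0], "k": gm.fr_holling[1]}
                if gm.fr_holling is not None
                else {"model": "linear", "slope": gm.fr_slope}
            ),
            "prey_cell_carbon_pg": gm.prey_cell_carbon_pg,
            "wells": self.truth,
        }


def simulate_experiment(
    gm: GeneratingModel,
    design: ExperimentDesign = ExperimentDesign(),
    seed: int = 0,
    noiseless: bool = False,
) -> SyntheticExperiment:
    """Simulate a full plate; identical seeds give bit-identical output."""
    rng = np.random.default_rng(seed)
    levels = food_series(design, rng)
    exp = SyntheticExperiment(design=design, generating_model=gm, seed=seed)
    for i, level in enumerate(levels):
        obs, truth = simulate_well(
            level, gm, design, rng, well_id=f"w{i:02d}", noiseless=noiseless
        )
        exp.wells.append(obs)
        exp.truth.append(truth)
    return exp


def parameter_recovery_suite(
    gm: GeneratingModel,
    design: ExperimentDesign = ExperimentDesign(),
    n_replicates: int = 100,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Repeatedly simulate, re-estimate, and score NR parameter recovery.

    For each replicate the plate is simulated with counting noise, the
    endpoint rates are computed, and the threshold numerical response is
    refit.  Reports per-parameter bias, RMSE, and Wald CI coverage of the
    generating truth, plus the replicate-level estimates.
    """
    truth = {"mu_max": gm.nr[0], "p_prime": gm.nr[1], "k2": gm.nr[2]}
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    rows = []
    failed = 0
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        exp = simulate_experiment(gm, design, seed=rep_seed)
        rates = rates_table(exp.wells)
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = NumericalResponse.from_rates(rates).fit()
        except Exception:
            failed += 1
            continue
        ci = res.conf_int(alpha=1 - ci_level)
        row = {"replicate": rep, "seed": rep_seed}
        for j, name in enumerate(res.param_names):
            row[f"{name}_hat"] = float(res.params[j])
            row[f"{name}_se"] = float(res.bse[j])
            row[f"{name}_cover"] = bool(ci[j, 0] <= truth[name] <= ci[j, 1])
        rows.append(row)
    estimates = pd.DataFrame(rows)
    report = {"truth": truth, "n_replicates": n_replicates, "n_failed": failed, "parameters": {}}
    for name, tv in truth.items():
        est = estimates[f"{name}_hat"].to_numpy()
        report["parameters"][name] = {
            "truth": tv,
            "mean": float(est.mean()),
            "bias": float(est.mean() - tv),
            "rmse": float(np.sqrt(np.mean((est - tv) ** 2))),
            "coverage": float(estimates[f"{name}_cover"].mean()),
        }
    report["estimates"] = estimates
    return report
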