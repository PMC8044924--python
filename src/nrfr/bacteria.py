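"""Bacterial-contamination sensitivity analysis.

Non-axenic grazing experiments carry a bacterial background whose biomass
scales with the algal food level.  This module quantifies how much that
background could move the fitted response curves: a linear calibration of
bacterial biomass against algal biomass, a refit of the NR/FR curves on
the combined (algae + predicted bacteria) biomass, and a worst-case
clearance-based extrapolation of bacterial carbon uptake per predator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .response import FunctionalResponse, NumericalResponse

logger = logging.getLogger(__name__)

__all__ = [
    "BacterialRegression",
    "ClearanceScenario",
    "fit_bacteria_vs_algae",
    "combined_biomass_refit",
    "bacterial_uptake_extrapolation",
]


@dataclass(frozen=True)
class BacterialRegression:
    """OLS line: bacterial biomass vs algal biomass (both ng C/ml)."""

    slope: float  # (ng C/ml bacteria) per (ng C/ml algae)
    intercept: float  # ng C/ml
    r_squared: float
    n_points: int

    def predict(self, algal_ng_ml):
        """Predicted bacterial biomass, clipped at 0 (with a warning)."""
        algal_ng_ml = np.asarray(algal_ng_ml, dtype=float)
        pred = self.slope * algal_ng_ml + self.intercept
        if np.any(pred < 0):
            logger.warning(
                "bacterial regression predicts negative biomass at %d of %d levels; clipping to 0",
                int(np.sum(pred < 0)),
                pred.size,
            )
        return np.clip(pred, 0.0, None)


@dataclass(frozen=True)
class ClearanceScenario:
    """Worst-case bacterivory scenario for the uptake extrapolation."""

    clearance_ul_per_h: float  # µl swept clear per predator per hour
    bacterial_density: float  # cells/ml
    per_cell_carbon_fg: float  # fg C/cell

    def __post_init__(self) -> None:
        if min(self.clearance_ul_per_h, self.per_cell_carbon_fg) <= 0 or self.bacterial_density < 0:
            raise ValueError("clearance and per-cell carbon must be > 0, density >= 0")


def fit_bacteria_vs_algae(algal_ng_ml, bacterial_ng_ml) -> BacterialRegression:
    """Ordinary least-squares calibration line through >= 2 points."""
    x = np.asarray(algal_ng_ml, dtype=float)
    y = np.asarray(bacterial_ng_ml, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired calibration points")
    if np.ptp(x) == 0:
        raise ValueError("identical algal levels: singular design")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return BacterialRegression(float(slope), float(intercept), r2, x.size)


def combined_biomass_refit(rates, reg: BacterialRegression) -> dict:
    """Refit NR and FR with bacterial biomass added to the prey axis.

    ``rates`` is a rates-table DataFrame (algae-only prey carbon).  Each
    well's geometric-mean prey biomass is augmented by the regression's
    predicted bacterial biomass at that level, both responses are refit,
    and the parameter shifts relative to the algae-only fits returned.
    """
    corrected = rates.copy()
    extra = reg.predict(corrected["p_mean_ngC_per_ml"].to_numpy())
    corrected["p_mean_ngC_per_ml"] = corrected["p_mean_ngC_per_ml"] + extra
    corrected["p_mean_mgC_per_liter"] = corrected["p_mean_ngC_per_ml"] / 1000.0

    nr0 = NumericalResponse.from_rates(rates).fit()
    nr1 = NumericalResponse.from_rates(corrected).fit()
    fr0 = FunctionalResponse.from_rates(rates).fit()
    fr1 = FunctionalResponse.from_rates(corrected).fit()

    deltas = {
        name: float(nr1.params[j] - nr0.params[j])
        for j, name in enumerate(nr0.param_names)
    }
    return {
        "nr_original": nr0,
        "nr_corrected": nr1,
        "fr_original": fr0,
        "fr_corrected": fr1,
        "nr_deltas": deltas,
    }


def bacterial_uptake_extrapolation(
    s: ClearanceScenario, fr_i_max: Optional[float] = None
) -> dict:
    """Clearance-based bacterial carbon uptake per predator.

    cells/h = clearance (ml/h) x density; carbon follows from the
    per-cell content; the daily rate is x24.  When an FR maximum
    ingestion rate is supplied, the implied additive shift of I_max and
    its relative magnitude are reported too.
    """
    clearance_ml_h = s.clearance_ul_per_h * 1e-3
    cells_per_h = clearance_ml_h * s.bacterial_density
    ng_per_h = cells_per_h * s.per_cell_carbon_fg * 1e-6
    ng_per_d = ng_per_h * 24.0
    out = {
        "cells_per_predator_h": cells_per_h,
        "ngC_per_predator_h": ng_per_h,
        "ngC_per_predator_d": ng_per_d,
    }
    if fr_i_max is not None and fr_i_max > 0:
        out["i_max_shift_ngC_per_d"] = ng_per_d
        out["i_max_relative_increase"] = ng_per_d / fr_i_max
    return out


def geometric_mean_after_doublings(initial_density: float, doublings: float) -> float:
    """Geometric-mean density of a population doubling ``doublings`` times.

    Worst-case arithmetic for bacterial background growth during an
    incubation: final = initial * 2**doublings, averaged with the same
    (final-initial)/ln(final/initial) time average used for the prey.
    """
    if initial_density <= 0:
        raise ValueError("initial density must be > 0")
    if doublings == 0:
        return initial_density
    final = initial_density * 2.0**doublings
    return (final - initial_density) / np.log(final / initial_density)
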