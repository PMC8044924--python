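"""Endpoint rate estimation for batch grazing incubations.

One experimental well yields four numbers per organism (initial/final
counts of predator and prey) plus a paired predator-free control.  Under
the assumption of exponential change between the two sampling points the
classic Frost/Heinbokel endpoint estimators give:

* predator specific growth      mu = ln(Nt/N0) / t
* geometric-mean prey level     P  = (Pt - P0) / ln(Pt/P0)
* grazing rate                  g  = [ln(Ct/C0) - ln(Pt/P0)] / t
* ingestion per predator        I  = P * g / Rm

with Rm the mean predator abundance over the incubation (geometric by
default).  All prey quantities are carried in carbon units (ng C/ml).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .units import NG_PER_PG

logger = logging.getLogger(__name__)

#: relative tolerance under which endpoint ratios are treated as unchanged
_REL_TOL = 1e-9


@dataclass(frozen=True)
class WellObservation:
    """Endpoint observations for one treatment well and its paired control.

    Counts are per ml.  ``prey_cell_carbon_pg`` converts prey cell counts
    to carbon.  ``duration_d`` is the incubation length in days.
    """

    well_id: str
    species: str
    temperature_c: float
    n0: float  # predators/ml at t0
    nt: float  # predators/ml at t_end
    p0: float  # prey cells/ml at t0 (treatment)
    pt: float  # prey cells/ml at t_end (treatment)
    c0: float  # prey cells/ml at t0 (control)
    ct: float  # prey cells/ml at t_end (control)
    duration_d: float
    prey_cell_carbon_pg: float

    def __post_init__(self) -> None:
        if self.duration_d <= 0:
            raise ValueError(f"{self.well_id}: duration must be > 0 d")
        if self.n0 <= 0 or self.p0 <= 0 or self.c0 <= 0:
            raise ValueError(f"{self.well_id}: initial counts must be > 0")
        if min(self.nt, self.pt, self.ct) < 0:
            raise ValueError(f"{self.well_id}: final counts must be >= 0")
        if self.prey_cell_carbon_pg <= 0:
            raise ValueError(f"{self.well_id}: prey cell carbon must be > 0")


@dataclass
class RateRecord:
    """Derived per-well rates with QC flags."""

    well_id: str
    species: str
    temperature_c: float
    mu: Optional[float]  # d^-1; None when the predator went extinct
    p_mean_ng_ml: float  # geometric-mean prey biomass, ng C/ml
    g: float  # grazing rate, d^-1
    rm: float  # mean predator abundance, per ml
    ingestion_ng_per_cell_d: float
    flags: list = field(default_factory=list)

    @property
    def p_mean_mg_l(self) -> float:
        return self.p_mean_ng_ml / 1000.0

    @property
    def extinct(self) -> bool:
        return "extinct" in self.flags


def growth_rate_endpoint(n0: float, nt: float, t: float) -> float:
    """Specific growth rate mu = ln(Nt/N0)/t in d^-1; negative permitted."""
    if n0 <= 0 or nt <= 0 or t <= 0:
        raise ValueError("growth_rate_endpoint requires N0 > 0, Nt > 0, t > 0")
    return math.log(nt / n0) / t


def geometric_mean_prey(p0: float, pt: float) -> float:
    """Time-averaged level of an exponentially changing quantity.

    (Pt - P0)/ln(Pt/P0), continuous at Pt == P0 where it returns P0.
    Symmetric in its arguments and always between min and max.
    """
    if p0 <= 0 or pt <= 0:
        raise ValueError("geometric_mean_prey requires positive endpoints")
    if math.isclose(p0, pt, rel_tol=_REL_TOL):
        return p0
    return (pt - p0) / math.log(pt / p0)


def geometric_mean_prey_verbatim(p0: float, pt: float) -> float:
    """Literal form (Pt-P0)/ln(Pt-P0) — dimensionally inconsistent, kept
    only for auditing against sources that print it; do not use in fits."""
    diff = pt - p0
    if diff <= 0 or math.isclose(diff, 1.0):
        raise ValueError("verbatim form undefined for Pt - P0 <= 0 or == 1")
    return diff / math.log(diff)


def grazing_rate(c0: float, ct: float, p0: float, pt: float, t: float) -> float:
    """Grazing rate g = [ln(Ct/C0) - ln(Pt/P0)]/t: control prey growth
    minus apparent prey growth in the grazed treatment."""
    if min(c0, ct, p0, pt) <= 0 or t <= 0:
        raise ValueError("grazing_rate requires positive abundances and duration")
    return (math.log(ct / c0) - math.log(pt / p0)) / t


def mean_predator_abundance(n0: float, nt: float, kind: str = "geometric") -> float:
    """Mean predator abundance over the incubation.

    ``geometric`` uses the same (Nt-N0)/ln(Nt/N0) time average as the prey;
    ``arithmetic`` is (N0+Nt)/2.
    """
    if n0 <= 0 or nt <= 0:
        raise ValueError("mean_predator_abundance requires positive counts")
    if kind == "arithmetic":
        return 0.5 * (n0 + nt)
    if kind != "geometric":
        raise ValueError("kind must be 'geometric' or 'arithmetic'")
    if math.isclose(n0, nt, rel_tol=_REL_TOL):
        return n0
    return (nt - n0) / math.log(nt / n0)


def ingestion_rate(
    p_mean: float, g: float, rm: float, clip_negative: bool = True
) -> float:
    """Per-predator ingestion I = P_mean * g / Rm (ng C/predator/d).

    With ``clip_negative`` (default) a negative grazing signal yields
    I = 0 rather than a physically impossible negative ingestion.
    """
    if rm <= 0:
        raise ValueError("ingestion_rate requires Rm > 0")
    if p_mean < 0:
        raise ValueError("ingestion_rate requires P_mean >= 0")
    raw = p_mean * g / rm
    if raw < 0 and clip_negative:
        return 0.0
    return raw


def compute_rates(
    well: WellObservation,
    rm_kind: str = "geometric",
    clip_negative_ingestion: bool = True,
) -> RateRecord:
    """All endpoint rates for one well, with QC flags.

    A zero final predator count marks the record ``extinct`` (mu is left
    undefined rather than -inf); negative grazing is retained but flagged.
    """
    flags: list = []
    m_ng = well.prey_cell_carbon_pg * NG_PER_PG
    p0_c = well.p0 * m_ng
    pt_c = well.pt * m_ng

    if well.nt == 0:
        flags.append("extinct")
        logger.warning("well %s: predator extinct at endpoint; mu undefined", well.well_id)
        mu = None
        rm = well.n0  # best available; record is excluded from fits anyway
    else:
        mu = growth_rate_endpoint(well.n0, well.nt, well.duration_d)
        rm = mean_predator_abundance(well.n0, well.nt, rm_kind)

    if well.pt == 0 or well.ct == 0:
        flags.append("prey_depleted")
        p_mean = geometric_mean_prey(p0_c, max(pt_c, 1e-12))
        g = float("nan")
        ingestion = float("nan")
    else:
        p_mean = geometric_mean_prey(p0_c, pt_c)
        g = grazing_rate(well.c0, well.ct, well.p0, well.pt, well.duration_d)
        if g < 0:
            flags.append("negative_grazing")
        ingestion = ingestion_rate(p_mean, g, rm, clip_negative_ingestion)
        if g < 0 and clip_negative_ingestion:
            flags.append("ingestion_clipped")

    return RateRecord(
        well_id=well.well_id,
        species=well.species,
        temperature_c=well.temperature_c,
        mu=mu,
        p_mean_ng_ml=p_mean,
        g=g,
        rm=rm,
        ingestion_ng_per_cell_d=ingestion,
        flags=flags,
    )


def rates_table(wells, **kwargs) -> pd.DataFrame:
    """Rate records for a collection of wells as a tidy DataFrame.

    Columns carry units in their names; ``flags`` is a semicolon-joined
    string so the table round-trips through CSV.
    """
    records = [compute_rates(w, **kwargs) for w in wells]
    return pd.DataFrame(
        {
            "well_id": [r.well_id for r in records],
            "species": [r.species for r in records],
            "temperature_C": [r.temperature_c for r in records],
            "mu_per_d": [r.mu for r in records],
            "p_mean_ngC_per_ml": [r.p_mean_ng_ml for r in records],
            "p_mean_mgC_per_liter": [r.p_mean_mg_l for r in records],
            "grazing_per_d": [r.g for r in records],
            "mean_predators_per_ml": [r.rm for r in records],
            "ingestion_ngC_per_cell_d": [r.ingestion_ng_per_cell_d for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
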