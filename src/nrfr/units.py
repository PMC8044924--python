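"""Strict carbon-concentration units shared across the package.

The canonical internal unit for prey biomass concentration is ng C/ml.
Figures and fitted response-curve parameters are conventionally reported
in mg C/liter; the two are related by an exact factor of 1000
(1 mg C/liter = 1000 ng C/ml), so conversions are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NG_PER_ML_PER_MG_PER_L = 1000.0

# per-cell carbon unit factors, expressed in ng
NG_PER_PG = 1e-3
NG_PER_FG = 1e-6


def mg_per_liter_to_ng_per_ml(value: float) -> float:
    """Convert mg C/liter to the canonical ng C/ml (exact)."""
    return value * NG_PER_ML_PER_MG_PER_L


def ng_per_ml_to_mg_per_liter(value: float) -> float:
    """Convert ng C/ml back to mg C/liter (exact)."""
    return value / NG_PER_ML_PER_MG_PER_L


@dataclass(frozen=True)
class BiomassConcentration:
    """A carbon biomass concentration, stored canonically in ng C/ml.

    Parameters
    ----------
    ng_per_ml : float
        Concentration in ng C/ml; must be non-negative.
    provenance : str
        One of ``measured``, ``converted``, ``simulated``.
    """

    ng_per_ml: float
    provenance: str = field(default="converted")

    _PROVENANCES = ("measured", "converted", "simulated")

    def __post_init__(self) -> None:
        if self.ng_per_ml < 0:
            raise ValueError(f"biomass concentration must be >= 0, got {self.ng_per_ml}")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")

    @classmethod
    def from_mg_per_liter(cls, value: float, provenance: str = "converted") -> "BiomassConcentration":
        return cls(mg_per_liter_to_ng_per_ml(value), provenance)

    @property
    def mg_per_liter(self) -> float:
        return ng_per_ml_to_mg_per_liter(self.ng_per_ml)
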