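"""Cell geometry and biovolume-to-carbon allometry.

Cell volumes are computed from length/width morphometry under a small set
of standard geometric idealizations (prolate ellipsoid for free-swimming
peritrichs, flattened ellipsoid for laterally compressed hymenostomes,
rod for bacteria, sphere for roughly isodiametric algae).  Volumes are
converted to per-cell carbon with class-specific power laws C = a * V**b:
the Menden-Deuer & Lessard laws for ciliates (pg C, coefficient 0.216,
exponent 0.939) and small algae (pg C, 0.261, 0.860), and the Romanova &
Sazhin law for bacterioplankton (fg C, 133.754, 0.438).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

from .units import NG_PER_FG, NG_PER_PG, BiomassConcentration

SHAPES = ("prolate_ellipsoid", "flattened_ellipsoid", "rod", "sphere")

#: Conventional depth:width ratio for flattened ellipsoids when no direct
#: depth measurement exists.
DEFAULT_DEPTH_TO_WIDTH = 2.0 / 3.0


@dataclass(frozen=True)
class CellMorphometry:
    """Length/width morphometry of a single cell type.

    length and width are in µm.  ``depth_to_width_ratio`` is only used for
    the flattened ellipsoid and must lie in (0, 1].
    """

    length: float
    width: float
    shape: str
    depth_to_width_ratio: float = DEFAULT_DEPTH_TO_WIDTH

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError(
                f"cell dimensions must be positive, got length={self.length}, width={self.width}"
            )
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if not (0 < self.depth_to_width_ratio <= 1):
            raise ValueError("depth_to_width_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class CarbonLaw:
    """Power-law biovolume-to-carbon conversion C = a * V**b.

    ``coefficient`` has units of ``output_unit`` per (µm³)**b; the output
    unit (pg or fg C per cell) is fixed per law and never inferred.
    """

    coefficient: float
    exponent: float
    output_unit: str  # "pg" or "fg"
    applicable_class: str  # "ciliate", "alga", "bacterium"
    name: str = ""

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("carbon-law coefficient must be > 0")
        if not (0 < self.exponent <= 1.5):
            raise ValueError("carbon-law exponent must lie in (0, 1.5]")
        if self.output_unit not in ("pg", "fg"):
            raise ValueError("output_unit must be 'pg' or 'fg'")

    @property
    def ng_factor(self) -> float:
        return NG_PER_PG if self.output_unit == "pg" else NG_PER_FG


#: Built-in named conversion laws.
BUILTIN_LAWS = {
    "menden_deuer_ciliate": CarbonLaw(0.216, 0.939, "pg", "ciliate", "menden_deuer_ciliate"),
    "menden_deuer_alga": CarbonLaw(0.261, 0.860, "pg", "alga", "menden_deuer_alga"),
    "romanova_bacterium": CarbonLaw(133.754, 0.438, "fg", "bacterium", "romanova_bacterium"),
}


def get_law(name_or_law) -> CarbonLaw:
    if isinstance(name_or_law, CarbonLaw):
        return name_or_law
    try:
        return BUILTIN_LAWS[name_or_law]
    except KeyError:
        raise KeyError(
            f"unknown carbon law {name_or_law!r}; built-ins: {sorted(BUILTIN_LAWS)}"
        ) from None


def ellipsoid_volume(morph: CellMorphometry) -> float:
    """Cell volume in µm³ for a given morphometry.

    prolate ellipsoid: (π/6)·L·W²;  flattened ellipsoid: (π/6)·L·W·(r·W)
    with r the depth:width ratio;  rod: cylinder π·(W/2)²·L;  sphere:
    (π/6)·L³ with the length taken as the diameter (L must equal W).
    """
    L, W = morph.length, morph.width
    if morph.shape == "prolate_ellipsoid":
        return math.pi / 6.0 * L * W * W
    if morph.shape == "flattened_ellipsoid":
        return math.pi / 6.0 * L * W * (morph.depth_to_width_ratio * W)
    if morph.shape == "rod":
        return math.pi * (W / 2.0) ** 2 * L
    # sphere
    if not math.isclose(L, W, rel_tol=1e-9):
        raise ValueError("sphere requires length == width (both are the diameter)")
    return math.pi / 6.0 * L**3


def biovolume_to_carbon(volume: float, law) -> float:
    """Per-cell carbon from volume (µm³) under a power law.

    Returns carbon in the law's own output unit (pg or fg per cell).
    """
    law = get_law(law)
    if volume <= 0:
        raise ValueError(f"cell volume must be > 0, got {volume}")
    return law.coefficient * volume**law.exponent


def cell_carbon_ng(volume: float, law) -> float:
    """Per-cell carbon in ng, regardless of the law's native unit."""
    law = get_law(law)
    return biovolume_to_carbon(volume, law) * law.ng_factor


def concentration_to_biomass(
    abundance: float,
    per_cell_carbon: float,
    unit: str = "pg",
    provenance: str = "converted",
) -> BiomassConcentration:
    """Convert cell abundance (cells/ml) and per-cell carbon to biomass.

    ``unit`` gives the unit of ``per_cell_carbon`` ("pg" or "fg"); output
    is canonical ng C/ml with an mg C/liter view on the returned object.
    """
    if abundance < 0:
        raise ValueError(f"abundance must be >= 0, got {abundance}")
    if per_cell_carbon <= 0:
        raise ValueError(f"per-cell carbon must be > 0, got {per_cell_carbon}")
    if unit == "pg":
        factor = NG_PER_PG
    elif unit == "fg":
        factor = NG_PER_FG
    elif unit == "ng":
        factor = 1.0
    else:
        raise ValueError("unit must be 'pg', 'fg' or 'ng'")
    return BiomassConcentration(abundance * per_cell_carbon * factor, provenance)


def load_laws(path) -> dict:
    """Read carbon laws from a YAML config.

    Schema: a mapping of law name to {coefficient, exponent, output_unit,
    applicable_class}.  Names shadow built-ins on collision.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    laws = dict(BUILTIN_LAWS)
    for name, spec in raw.items():
        laws[name] = CarbonLaw(
            coefficient=float(spec["coefficient"]),
            exponent=float(spec["exponent"]),
            output_unit=str(spec["output_unit"]),
            applicable_class=str(spec.get("applicable_class", "ciliate")),
            name=name,
        )
    return laws
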