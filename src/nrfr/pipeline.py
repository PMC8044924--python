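"""Plate-table I/O, run configuration, and the end-to-end report.

The single input dialect is a long/tidy CSV with one row per
well x organism x timepoint:

    well_id, species, temperature_C, role, organism, timepoint,
    count_per_ml, duration_d, prey_cell_carbon_pg

role is ``treatment`` or ``control``, organism ``predator`` or ``prey``,
timepoint ``t0`` or ``t2``.  Every treatment well carries its paired
control prey rows under the same well_id; a missing pairing falls back
to the nearest food level's control with a logged warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bacteria import combined_biomass_refit, fit_bacteria_vs_algae
from .rates import WellObservation, rates_table
from .response import (
    FunctionalResponse,
    NumericalResponse,
    gross_growth_efficiency,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "well_id",
    "species",
    "temperature_C",
    "role",
    "organism",
    "timepoint",
    "count_per_ml",
    "duration_d",
    "prey_cell_carbon_pg",
]

_ENUMS = {"role": {"treatment", "control"}, "organism": {"predator", "prey"}, "timepoint": {"t0", "t2"}}


class PlateTableError(ValueError):
    """Schema or pairing violation in a plate table, with row addresses."""


def _validate_rows(df: pd.DataFrame) -> list:
    problems = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        return problems
    for col, allowed in _ENUMS.items():
        bad = df.index[~df[col].isin(allowed)]
        for i in bad:
            problems.append(f"row {i}: {col}={df.at[i, col]!r} not in {sorted(allowed)}")
    bad = df.index[pd.to_numeric(df["count_per_ml"], errors="coerce").isna()]
    for i in bad:
        problems.append(f"row {i}: count_per_ml is not numeric")
    numeric = pd.to_numeric(df["count_per_ml"], errors="coerce")
    for i in df.index[numeric < 0]:
        problems.append(f"row {i}: negative count_per_ml ({df.at[i, 'count_per_ml']})")
    return problems


def read_plate_table(path) -> list:
    """Read and validate a long-format plate table into WellObservations."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round_trip parsing keeps simulator output bit-identical through CSV
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return plate_frame_to_wells(df)


def plate_frame_to_wells(df: pd.DataFrame) -> list:
    """Validate a plate DataFrame and assemble one observation per well."""
    problems = _validate_rows(df)
    if problems:
        raise PlateTableError("invalid plate table:\n  " + "\n  ".join(problems))

    wells = []
    controls_by_level = {}
    pending = []
    for well_id, grp in df.groupby("well_id", sort=False):
        meta = grp.iloc[0]

        def pick(role, organism, timepoint, g=grp, wid=well_id):
            sel = g[(g["role"] == role) & (g["organism"] == organism) & (g["timepoint"] == timepoint)]
            if len(sel) > 1:
                raise PlateTableError(f"well {wid}: duplicate {role}/{organism}/{timepoint} rows")
            if sel.empty:
                return None
            return float(sel["count_per_ml"].iloc[0])

        n0 = pick("treatment", "predator", "t0")
        nt = pick("treatment", "predator", "t2")
        p0 = pick("treatment", "prey", "t0")
        pt = pick("treatment", "prey", "t2")
        c0 = pick("control", "prey", "t0")
        ct = pick("control", "prey", "t2")
        missing = [k for k, v in dict(n0=n0, nt=nt, p0=p0, pt=pt).items() if v is None]
        if missing:
            raise PlateTableError(f"well {well_id}: missing required rows for {missing}")
        rec = dict(
            well_id=str(well_id),
            species=str(meta["species"]),
            temperature_c=float(meta["temperature_C"]),
            n0=n0,
            nt=nt,
            p0=p0,
            pt=pt,
            c0=c0,
            ct=ct,
            duration_d=float(meta["duration_d"]),
            prey_cell_carbon_pg=float(meta["prey_cell_carbon_pg"]),
        )
        if c0 is not None and ct is not None:
            controls_by_level[p0] = (c0, ct)
            wells.append(WellObservation(**rec))
        else:
            pending.append(rec)

    for rec in pending:  # pair controls by nearest nominal food level
        if not controls_by_level:
            raise PlateTableError(f"well {rec['well_id']}: no control rows anywhere in the table")
        nearest = min(controls_by_level, key=lambda lvl: abs(np.log(lvl / rec["p0"])))
        logger.warning(
            "well %s: no matched control; using control at food level %.3g cells/ml",
            rec["well_id"],
            nearest,
        )
        rec["c0"], rec["ct"] = controls_by_level[nearest]
        wells.append(WellObservation(**rec))
    return wells


def write_plate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and report


@dataclass
class RunConfig:
    """Configuration of an end-to-end analysis run."""

    input_path: Optional[str] = None
    output_dir: str = "nrfr_out"
    seed: int = 0
    reference_levels_mg_l: Sequence[float] = (0.5, 2.0)
    gge_level_mg_l: float = 0.5
    rm_kind: str = "geometric"  # mean predator abundance: geometric|arithmetic
    predator_cell_carbon_ng: Optional[float] = None  # enables GGE when set
    bacterial_calibration_path: Optional[str] = None  # Table of algal/bacterial levels
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fit_group(rates: pd.DataFrame, config: RunConfig) -> dict:
    out: dict = {}
    nr = NumericalResponse.from_rates(rates).fit()
    fr = FunctionalResponse.from_rates(rates).fit()
    out["nr"] = nr
    out["fr"] = fr
    out["predictions"] = {
        float(p): {"mu_per_d": float(nr.predict(p)), "ingestion_ngC_per_cell_d": float(fr.predict(p))}
        for p in config.reference_levels_mg_l
    }
    if config.predator_cell_carbon_ng is not None:
        p = config.gge_level_mg_l
        mu = float(nr.predict(p))
        ing = float(fr.predict(p))
        if ing > 0:
            gge = gross_growth_efficiency(mu, config.predator_cell_carbon_ng, ing, p)
            out["gge"] = {"fraction": gge.gge, "percent": gge.percent, "food_level_mg_l": p}
    return out


def _fit_to_json(bundle: dict) -> dict:
    nr, fr = bundle["nr"], bundle["fr"]
    rec = {
        "nr": {
            "params": dict(zip(nr.param_names, map(float, nr.params))),
            "se": dict(zip(nr.param_names, map(float, nr.bse))),
            "pvalues": dict(zip(nr.param_names, map(float, nr.pvalues))),
            "alpha": float(nr.alpha),
            "alpha_se": float(nr.alpha_se),
            "aicc": float(nr.aicc),
            "flags": nr.flags,
        },
        "fr": {
            "selected": fr.selected,
            "holling_divergent": fr.holling_divergent,
            "linear": {k: float(v) for k, v in fr.linear.items()},
        },
        "predictions": bundle["predictions"],
    }
    if fr.holling is not None:
        rec["fr"]["holling_II"] = {
            "i_max": float(fr.holling["params"][0]),
            "k": float(fr.holling["params"][1]),
            "i_max_se": float(fr.holling["bse"][0]),
            "k_se": float(fr.holling["bse"][1]),
            "aicc": float(fr.holling["aicc"]),
            "flags": bundle["fr"].holling_flags,
        }
    if "gge" in bundle:
        rec["gge"] = bundle["gge"]
    if "bacterial_correction" in bundle:
        rec["bacterial_correction"] = bundle["bacterial_correction"]
    return rec


def run_report(config: RunConfig, wells: Optional[list] = None) -> dict:
    """Run the full pipeline and write the result bundle.

    Per species x temperature group: the rates table, NR and FR fits,
    predictions at the reference food levels, optional GGE and optional
    bacterial correction.  Outputs (CSV + JSON + manifest) land in
    ``config.output_dir``; the bundle is also returned in memory.
    """
    if wells is None:
        if config.input_path is None:
            raise ValueError("run_report needs either wells or config.input_path")
        wells = read_plate_table(config.input_path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates = rates_table(wells, rm_kind=config.rm_kind)
    rates.to_csv(outdir / "rates.csv", index=False)
    n_flagged = int((rates["flags"] != "").sum())
    logger.info("rates: %d wells, %d flagged", len(rates), n_flagged)

    calibration = None
    if config.bacterial_calibration_path:
        cal = pd.read_csv(config.bacterial_calibration_path)
        calibration = fit_bacteria_vs_algae(
            cal["algal_ngC_per_ml"].to_numpy(), cal["bacterial_ngC_per_ml"].to_numpy()
        )

    results: dict = {}
    for (species, temp), grp in rates.groupby(["species", "temperature_C"]):
        key = f"{species}@{temp:g}C"
        try:
            bundle = _fit_group(grp, config)
        except Exception as exc:  # stage-tagged partial failure
            logger.error("fit failed for %s: %s", key, exc)
            results[key] = {"error": str(exc)}
            continue
        if calibration is not None:
            corr = combined_biomass_refit(grp, calibration)
            bundle["bacterial_correction"] = {
                "regression": {
                    "slope": calibration.slope,
                    "intercept_ngC_per_ml": calibration.intercept,
                    "r_squared": calibration.r_squared,
                },
                "nr_deltas": corr["nr_deltas"],
                "nr_corrected": dict(
                    zip(corr["nr_corrected"].param_names, map(float, corr["nr_corrected"].params))
                ),
            }
        results[key] = bundle
        if config.make_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
            bundle["nr"].plot(ax=axes[0])
            bundle["fr"].plot(ax=axes[1])
            fig.suptitle(key)
            fig.tight_layout()
            fig.savefig(outdir / f"curves_{species}_{temp:g}C.png", dpi=120)
            plt.close(fig)

    serializable = {
        k: (_fit_to_json(v) if "error" not in v else v) for k, v in results.items()
    }
    manifest = {
        "nrfr_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_wells": len(wells),
        "n_flagged": n_flagged,
        "groups": sorted(serializable),
    }
    with open(outdir / "fits.json", "w") as fh:
        json.dump(serializable, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"rates": rates, "results": results, "manifest": manifest}
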