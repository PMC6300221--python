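"""Prediction of unknowns and aggregation into population hormone profiles.

Concentrations come out of the calibration models in µM of extract; tissue
content is reported in µg per g fresh weight via the extract volume and
tissue mass (the UnitContext).  Negative predictions — possible when a
sample sits outside the calibrated range — are flagged, not clipped, unless
clipping is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationError, predict_preprocessed
from .pls import PLSModel
from .spectra import SpectraSet

__all__ = [
    "UnitContext",
    "HormoneProfile",
    "predict_unknowns",
    "to_mass_per_fw",
    "from_mass_per_fw",
    "aggregate_population",
    "profiles_frame",
    "DEFAULT_MOLAR_MASS",
    "UnitError",
]

# Standard molar masses, g/mol (GA as gibberellic acid GA3).
DEFAULT_MOLAR_MASS: dict[str, float] = {
    "IAA": 175.18,
    "GA": 346.37,
    "SA": 138.12,
    "kinetin": 215.21,
}


class UnitError(ValueError):
    pass


@dataclass(frozen=True)
class UnitContext:
    """Conversion constants between extract molarity and tissue content.

    extract_volume_L defaults to 10 mL of methanol extract per 1.0 g fresh
    leaf tissue; both are explicit so the µM → µg/g step is never hidden.
    """

    molar_mass: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOLAR_MASS))
    extract_volume_L: float = 0.010
    tissue_mass_g: float = 1.0

    def __post_init__(self) -> None:
        if self.extract_volume_L <= 0 or self.tissue_mass_g <= 0:
            raise UnitError("extract volume and tissue mass must be > 0")
        for h, m in self.molar_mass.items():
            if m <= 0:
                raise UnitError(f"molar mass of {h} must be > 0")


@dataclass
class HormoneProfile:
    """Per-population mean ± SE tissue content for each hormone (µg/g FW)."""

    population: str
    mean: dict[str, float]
    se: dict[str, float]
    n_replicates: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise UnitError("n_replicates must be >= 1")
        for h, s in self.se.items():
            if s < 0:
                raise UnitError(f"negative SE for {h}")


def predict_unknowns(model: PLSModel, unknowns: SpectraSet,
                     clip_negative: bool = False) -> pd.DataFrame:
    """Predicted concentration (µM) per unknown sample for one model.

    Applies the model's frozen preprocessing (window, MSC reference) before
    prediction.  Returns a frame with sample_id, population, replicate,
    concentration_uM and a per-sample flag column ('negative' marks
    predictions below zero, which are kept as-is unless clip_negative).
    """
    yhat = predict_preprocessed(model, unknowns)
    flags = ["negative" if v < 0 else "" for v in yhat]
    if clip_negative:
        yhat = np.maximum(yhat, 0.0)
    meta = [unknowns.meta[sid] for sid in unknowns.sample_ids]
    return pd.DataFrame({
        "sample_id": unknowns.sample_ids,
        "population": [m.population for m in meta],
        "replicate": [m.replicate for m in meta],
        "concentration_uM": yhat,
        "flag": flags,
    })


def to_mass_per_fw(conc_uM, ctx: UnitContext, hormone: str):
    """µM extract concentration → µg analyte per g fresh tissue.

    c[µmol/L] * M[g/mol] gives µg/L; times extract volume, per tissue mass.
    """
    if hormone not in ctx.molar_mass:
        raise UnitError(f"no molar mass for {hormone!r}")
    c = np.asarray(conc_uM, dtype=float)
    out = c * ctx.molar_mass[hormone] * ctx.extract_volume_L / ctx.tissue_mass_g
    return float(out) if np.isscalar(conc_uM) else out


def from_mass_per_fw(ug_per_g, ctx: UnitContext, hormone: str):
    """Inverse of :func:`to_mass_per_fw` (µg/g FW → µM in the extract)."""
    if hormone not in ctx.molar_mass:
        raise UnitError(f"no molar mass for {hormone!r}")
    c = np.asarray(ug_per_g, dtype=float)
    out = c * ctx.tissue_mass_g / (ctx.molar_mass[hormone] * ctx.extract_volume_L)
    return float(out) if np.isscalar(ug_per_g) else out


def aggregate_population(per_sample: pd.DataFrame) -> list[HormoneProfile]:
    """Replicate-level values → per-population mean and standard error.

    ``per_sample`` needs columns population, hormone, value (one row per
    replicate measurement).  SE = sd/sqrt(n) with the n observed in the
    data; single-replicate populations get SE 0 and a flag.
    """
    required = {"population", "hormone", "value"}
    if not required.issubset(per_sample.columns):
        raise UnitError(f"need columns {sorted(required)}")
    profiles = []
    for pop, g in per_sample.groupby("population", sort=True):
        means: dict[str, float] = {}
        ses: dict[str, float] = {}
        flags: list[str] = []
        ns = []
        for hormone, gh in g.groupby("hormone", sort=True):
            vals = gh["value"].to_numpy(dtype=float)
            ns.append(len(vals))
            means[hormone] = float(vals.mean())
            if len(vals) == 1:
                ses[hormone] = 0.0
                flags.append(f"{hormone}:single-replicate")
            else:
                ses[hormone] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        profiles.append(HormoneProfile(population=str(pop), mean=means, se=ses,
                                       n_replicates=int(max(ns)), flags=flags))
    return profiles


def profiles_frame(profiles: list[HormoneProfile]) -> pd.DataFrame:
    """Long-format table: population, hormone, mean_ug_per_gfw, se, n, flags."""
    rows = []
    for p in profiles:
        for h in p.mean:
            rows.append({
                "population": p.population,
                "hormone": h,
                "mean_ug_per_gfw": p.mean[h],
                "se": p.se[h],
                "n": p.n_replicates,
                "flags": ";".join(f for f in p.flags if f.startswith(f"{h}:")),
            })
    return pd.DataFrame(
        rows, columns=["population", "hormone", "mean_ug_per_gfw", "se", "n", "flags"]
    )
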