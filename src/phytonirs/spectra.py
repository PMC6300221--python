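"""Data model and I/O for NIR absorption spectra.

Spectra live on a shared, strictly ascending, uniformly spaced wavenumber
grid (cm^-1); the instrument convention emulated here is 4000-10000 cm^-1
at 2 cm^-1 steps, recorded in absorption mode.  Files written with a
descending grid (the native instrument order) are normalized to ascending
on read, so derivative signs and window semantics are defined once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SampleMeta",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "restrict_window",
    "read_jcamp",
    "SpectraFormatError",
    "GridError",
    "MetadataError",
    "WindowError",
]

HORMONES = ("IAA", "GA", "SA", "kinetin")

_GRID_RTOL = 1e-6


class SpectraFormatError(ValueError):
    """Malformed spectra file (ragged rows, missing columns...)."""


class GridError(ValueError):
    """Wavenumber grid violates ordering/uniformity requirements."""


class MetadataError(ValueError):
    """Sample metadata violates its invariants."""


class WindowError(ValueError):
    """Requested wavenumber window does not intersect the grid."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise GridError("grid must be strictly ascending")
        step = d.mean()
        if np.max(np.abs(d - step)) > _GRID_RTOL * max(abs(step), 1.0):
            raise GridError("grid spacing non-uniform beyond tolerance")
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:  # value equality, not identity
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    @classmethod
    def default(cls, low: float = 4000.0, high: float = 10000.0, step: float = 2.0):
        return cls(np.arange(low, high + step / 2, step))


@dataclass
class Spectrum:
    """One absorbance trace on a grid, identified by sample_id."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise SpectraFormatError(
                f"{self.sample_id}: absorbance length {a.size} != grid length "
                f"{len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise SpectraFormatError(f"{self.sample_id}: non-finite absorbance")
        self.absorbance = a


@dataclass
class SampleMeta:
    """Role and labels for one sample.

    Standards carry analyte and concentration (µM); unknowns carry a
    population label (and usually a replicate index).
    """

    sample_id: str
    role: str
    analyte: str | None = None
    concentration_uM: float | None = None
    population: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("standard", "unknown"):
            raise MetadataError(f"{self.sample_id}: role must be standard|unknown")
        if self.role == "standard":
            if self.analyte is None or self.concentration_uM is None:
                raise MetadataError(
                    f"{self.sample_id}: standard requires analyte and concentration"
                )
            if self.concentration_uM < 0:
                raise MetadataError(f"{self.sample_id}: negative concentration")
        else:
            if not self.population:
                raise MetadataError(f"{self.sample_id}: unknown requires population")
        if self.replicate is not None and self.replicate < 1:
            raise MetadataError(f"{self.sample_id}: replicate must be >= 1")


@dataclass
class SpectraSet:
    """An ordered collection of spectra on one grid, with metadata."""

    grid: WavenumberGrid
    spectra: list[Spectrum]
    meta: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate sample_id in spectra")
        for s in self.spectra:
            if s.grid != self.grid:
                raise GridError(f"{s.sample_id}: grid differs from set grid")
            if s.sample_id not in self.meta:
                raise MetadataError(f"{s.sample_id}: no metadata entry")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    def as_matrix(self) -> np.ndarray:
        """(n_samples, n_wavenumbers) absorbance matrix in set order."""
        if not self.spectra:
            return np.empty((0, len(self.grid)))
        return np.vstack([s.absorbance for s in self.spectra])

    def subset(self, sample_ids: Iterable[str]) -> "SpectraSet":
        wanted = list(sample_ids)
        by_id = {s.sample_id: s for s in self.spectra}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise MetadataError(f"unknown sample_ids: {missing}")
        return SpectraSet(
            grid=self.grid,
            spectra=[by_id[i] for i in wanted],
            meta={i: self.meta[i] for i in wanted},
        )

    def concentrations(self) -> np.ndarray:
        """Concentration vector (µM) in set order; standards only."""
        out = []
        for s in self.spectra:
            m = self.meta[s.sample_id]
            if m.concentration_uM is None:
                raise MetadataError(f"{s.sample_id}: no concentration")
            out.append(m.concentration_uM)
        return np.asarray(out, dtype=float)


def _meta_from_frame(df: pd.DataFrame) -> dict[str, SampleMeta]:
    required = {"sample_id", "role"}
    if not required.issubset(df.columns):
        raise MetadataError(f"metadata file needs columns {sorted(required)}")
    meta: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in meta:
            raise MetadataError(f"duplicate sample_id {sid!r} in metadata")

        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) or v == "" else v

        conc = _opt("concentration_uM")
        rep = _opt("replicate")
        meta[sid] = SampleMeta(
            sample_id=sid,
            role=str(row["role"]),
            analyte=None if _opt("analyte") is None else str(_opt("analyte")),
            concentration_uM=None if conc is None else float(conc),
            population=None if _opt("population") is None else str(_opt("population")),
            replicate=None if rep is None else int(rep),
        )
    return meta


def read_spectra(spectra_path, meta_path) -> SpectraSet:
    """Read a wide-format spectra CSV plus a metadata CSV.

    The spectra file has a first column ``wavenumber_cm1`` and one column
    per sample; rows may be in ascending or descending wavenumber order
    (descending files are flipped to the internal ascending convention).
    """
    try:
        df = pd.read_csv(spectra_path)
    except pd.errors.ParserError as e:
        raise SpectraFormatError(f"malformed spectra CSV: {e}") from e
    if df.columns[0] != "wavenumber_cm1":
        raise SpectraFormatError("first column must be 'wavenumber_cm1'")
    if df.isna().any().any():
        raise SpectraFormatError("ragged or missing values in spectra CSV")
    wn = df["wavenumber_cm1"].to_numpy(dtype=float)
    if wn.size >= 2 and wn[0] > wn[-1]:  # descending file → normalize
        df = df.iloc[::-1].reset_index(drop=True)
        wn = df["wavenumber_cm1"].to_numpy(dtype=float)
    grid = WavenumberGrid(wn)

    meta = _meta_from_frame(pd.read_csv(meta_path, dtype={"sample_id": str}))
    spectra = []
    for col in df.columns[1:]:
        sid = str(col)
        if sid not in meta:
            raise MetadataError(f"spectrum {sid!r} has no metadata row")
        spectra.append(
            Spectrum(grid=grid, absorbance=df[col].to_numpy(dtype=float), sample_id=sid)
        )
    return SpectraSet(grid=grid, spectra=spectra, meta=meta)


def write_spectra(sset: SpectraSet, spectra_path, meta_path) -> None:
    """Write the wide-format spectra CSV and metadata CSV (ascending grid).

    Round-trips through :func:`read_spectra` to 1e-12 relative.
    """
    cols = {"wavenumber_cm1": sset.grid.values}
    for s in sset.spectra:
        cols[s.sample_id] = s.absorbance
    pd.DataFrame(cols).to_csv(spectra_path, index=False, float_format="%.17g")

    rows = []
    for s in sset.spectra:
        m = sset.meta[s.sample_id]
        rows.append(
            {
                "sample_id": m.sample_id,
                "role": m.role,
                "analyte": m.analyte or "",
                "concentration_uM": "" if m.concentration_uM is None else m.concentration_uM,
                "population": m.population or "",
                "replicate": "" if m.replicate is None else m.replicate,
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample_id", "role", "analyte", "concentration_uM", "population", "replicate"],
    ).to_csv(meta_path, index=False)


def restrict_window(sset: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep only grid points with low <= wavenumber <= high (closed interval).

    Exact grid points only — no interpolation; metadata is preserved.
    """
    if not low < high:
        raise WindowError(f"window low {low} must be < high {high}")
    mask = (sset.grid.values >= low) & (sset.grid.values <= high)
    if mask.sum() < 2:
        raise WindowError(f"window [{low}, {high}] does not intersect the grid")
    if mask.all():
        return sset
    grid = WavenumberGrid(sset.grid.values[mask])
    spectra = [
        Spectrum(grid=grid, absorbance=s.absorbance[mask], sample_id=s.sample_id)
        for s in sset.spectra
    ]
    return SpectraSet(grid=grid, spectra=spectra, meta=dict(sset.meta))


def read_jcamp(path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for a single ``##XYDATA=(X++(Y..Y))`` block.

    Returns (wavenumbers ascending, absorbance).  Uses XFACTOR/YFACTOR when
    present; AFFN (plain decimal) tables only.
    """
    text = Path(path).read_text()
    xfac = yfac = 1.0
    m = re.search(r"##XFACTOR=\s*([-\d.eE+]+)", text)
    if m:
        xfac = float(m.group(1))
    m = re.search(r"##YFACTOR=\s*([-\d.eE+]+)", text)
    if m:
        yfac = float(m.group(1))
    m = re.search(r"##XYDATA=\(X\+\+\(Y\.\.Y\)\)\s*\n(.*?)(?:##END|$)", text, re.S)
    if not m:
        raise SpectraFormatError("no ##XYDATA=(X++(Y..Y)) block found")
    xs: list[float] = []
    ys: list[float] = []
    lines = [ln for ln in m.group(1).strip().splitlines() if ln.strip()]
    for ln in lines:
        vals = [float(t) for t in re.split(r"[\s,]+", ln.strip()) if t]
        if len(vals) < 2:
            raise SpectraFormatError(f"bad XYDATA line: {ln!r}")
        x0, yvals = vals[0], vals[1:]
        xs.append(x0)
        ys.append(yvals)
    # reconstruct per-point x from line starts (uniform step within lines)
    all_x: list[float] = []
    all_y: list[float] = []
    for i, (x0, yvals) in enumerate(zip(xs, ys)):
        if i + 1 < len(xs):
            step = (xs[i + 1] - x0) / len(yvals)
        elif len(all_x) >= 2:
            step = all_x[1] - all_x[0]
        elif len(yvals) > 1:
            step = 0.0  # single line, unknowable without more info
        else:
            step = 0.0
        for j, y in enumerate(yvals):
            all_x.append(x0 + j * step)
            all_y.append(y)
    x = np.asarray(all_x) * xfac
    y = np.asarray(all_y) * yfac
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return x, y
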