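"""Synthetic NIR spectra with known ground truth.

Beer-Lambert mixtures: each analyte contributes Gaussian absorption bands
(amplitude proportional to concentration) at its characteristic combination
and overtone positions; a broad matrix/solvent interferent is added at a
fixed level; instrument artefacts are emulated with a multiplicative
scatter factor, an additive offset, a linear baseline tilt and white noise:

    x -> b * x + a + tilt * (nu - nu0) / range + eps

Band *centers* follow the published assignments for the four hormones
(each hormone's strongest feature is a combination band the assignments
place uniquely: IAA N-H 4500, GA R-OH 4700, SA O-H 5000, kinetin C-N
5100 cm^-1).  Widths and amplitudes are package constants chosen so the
four signatures stay spectrally separable: 15 cm^-1 sigma in the
combination region, 120 cm^-1 for overtones, dominant-band amplitude
0.004 AU/µM (≈1 AU at the 250 µM top standard), shared bands weak.  The
interferent sits in analyte-free zones (7800, 9800 cm^-1) where it doubles
as a stable intensity reference against multiplicative scatter — mimicking
a solvent feature rather than overlapping the analytical bands.  Default
noise is multiplicative scatter plus detector white noise; additive offset
and baseline tilt default to zero (absorption-mode spectra are referenced
against a solvent background, which cancels additive terms) but both are
available for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    HORMONES,
    SampleMeta,
    SpectraSet,
    Spectrum,
    WavenumberGrid,
)

__all__ = [
    "Band",
    "AnalyteSignature",
    "NoiseModel",
    "default_signatures",
    "pure_spectrum",
    "generate_standards",
    "generate_extracts",
    "SimulationError",
    "DEFAULT_INTERFERENT_LEVEL_UM",
]

DEFAULT_INTERFERENT_LEVEL_UM = 50.0

GRID_LOW, GRID_HIGH = 4000.0, 10000.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center (cm^-1), sigma (cm^-1),
    amplitude (AU per µM)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SimulationError("band width must be > 0")
        if self.amplitude < 0:
            raise SimulationError("band amplitude must be >= 0")
        if not (GRID_LOW <= self.center <= GRID_HIGH):
            raise SimulationError(f"band center {self.center} outside {GRID_LOW}-{GRID_HIGH}")


@dataclass(frozen=True)
class AnalyteSignature:
    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if self.name not in HORMONES and self.name != "interferent":
            raise SimulationError(f"unknown analyte {self.name!r}")
        if not self.bands:
            raise SimulationError("signature needs at least one band")


@dataclass
class NoiseModel:
    """Instrument/scatter artefact model (all sigmas >= 0; zeros = clean)."""

    mult_sigma: float = 0.005    # lognormal sigma of the scatter slope b
    add_sigma: float = 0.0       # normal sigma of the additive offset a, AU
    tilt_sigma: float = 0.0      # normal sigma of baseline tilt over full range, AU
    white_sigma: float = 0.004   # per-point white noise, AU
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mult_sigma", "add_sigma", "tilt_sigma", "white_sigma"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, seed)

    def apply(self, X: np.ndarray, grid: WavenumberGrid,
              rng: np.random.Generator) -> np.ndarray:
        """Apply one artefact realization per row of X."""
        X = np.atleast_2d(X)
        n = X.shape[0]
        b = np.exp(rng.normal(0.0, self.mult_sigma, size=n)) if self.mult_sigma else np.ones(n)
        a = rng.normal(0.0, self.add_sigma, size=n) if self.add_sigma else np.zeros(n)
        tilt = rng.normal(0.0, self.tilt_sigma, size=n) if self.tilt_sigma else np.zeros(n)
        v = grid.values
        ramp = (v - v[0]) / (v[-1] - v[0])
        out = b[:, None] * X + a[:, None] + tilt[:, None] * ramp[None, :]
        if self.white_sigma:
            out = out + rng.normal(0.0, self.white_sigma, size=out.shape)
        return out


# Dominant combination bands get 4e-3 AU/µM at hormone-unique centers;
# bands shared between hormones are kept weak (2e-5) and overtone
# secondaries moderate (2-3e-4) so pairwise spectral cross-talk stays ~1%
# at the concentration ratios seen in leaf extracts.
_SIG = 15.0    # combination-region sigma
_SIGO = 120.0  # overtone-region sigma
_DOM = 4.0e-3
_MINOR = 2.0e-5

_DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    # C-H/CH2 combination 4150, N-H combination 4500 (dominant), C=O 5200,
    # aromatic C-H 1st overtone 5900, O-H 1st overtone 7100, aromatic C-H
    # 2nd overtone 9100
    "IAA": ((4150, _SIG, _MINOR), (4500, _SIG, _DOM), (5200, _SIG, _MINOR),
            (5900, _SIGO, 3e-4), (7100, _SIGO, _MINOR), (9100, _SIGO, 2e-4)),
    # C-H combination 4500, R-OH 4700 (dominant), C=O 5200, 7000-7300 overtones
    "GA": ((4500, _SIG, _MINOR), (4700, _SIG, _DOM), (5200, _SIG, _MINOR),
           (7150, _SIGO, _MINOR)),
    # C-H/CH2 combination 4150, O-H combination 5000 (dominant), C=O 5200,
    # aromatic O-H 1st overtone 7100
    "SA": ((4150, _SIG, _MINOR), (5000, _SIG, _DOM), (5200, _SIG, _MINOR),
           (7100, _SIGO, _MINOR)),
    # N-H combination 4400, C-N combination 5100 (dominant), N-H 1st
    # overtone 6700, C-H 2nd overtone 8800
    "kinetin": ((4400, _SIG, _MINOR), (5100, _SIG, _DOM),
                (6700, _SIGO, 3e-4), (8800, _SIGO, 2e-4)),
    # broad solvent/matrix background in analyte-free zones
    "interferent": ((7800, 150.0, 4e-3), (9800, 100.0, 4e-3)),
}


def default_signatures() -> list[AnalyteSignature]:
    """Built-in band library for the four hormones plus the matrix interferent."""
    return [
        AnalyteSignature(name=name, bands=tuple(Band(*b) for b in bands))
        for name, bands in _DEFAULT_BANDS.items()
    ]


def _signature_map(signatures) -> dict[str, AnalyteSignature]:
    return {s.name: s for s in signatures}


def pure_spectrum(
    signature: AnalyteSignature, concentration_uM: float, grid: WavenumberGrid,
    sample_id: str = "pure",
) -> Spectrum:
    """Noise-free Beer-Lambert spectrum: c * sum of Gaussian bands."""
    if concentration_uM < 0:
        raise SimulationError("concentration must be >= 0")
    v = grid.values
    a = np.zeros_like(v)
    for b in signature.bands:
        a += b.amplitude * np.exp(-((v - b.center) ** 2) / (2.0 * b.width**2))
    return Spectrum(grid=grid, absorbance=concentration_uM * a, sample_id=sample_id)


def _clean_signal(conc: dict[str, float], sigs: dict[str, AnalyteSignature],
                  grid: WavenumberGrid, interferent_uM: float) -> np.ndarray:
    a = np.zeros(len(grid))
    for name, c in conc.items():
        a += pure_spectrum(sigs[name], c, grid).absorbance
    if interferent_uM and "interferent" in sigs:
        a += pure_spectrum(sigs["interferent"], interferent_uM, grid).absorbance
    return a


def concentration_levels(levels: int = 65, c_min: float = 0.1,
                         c_max: float = 250.0, spacing: str = "log") -> np.ndarray:
    """The standards concentration series (µM); log-spaced by default."""
    if levels < 2:
        raise SimulationError("need at least 2 concentration levels")
    if spacing == "log":
        if c_min <= 0:
            raise SimulationError("log spacing requires c_min > 0")
        return np.geomspace(c_min, c_max, levels)
    if spacing == "linear":
        return np.linspace(c_min, c_max, levels)
    raise SimulationError(f"unknown spacing {spacing!r}")


def generate_standards(
    signatures=None,
    levels: int = 65,
    c_min: float = 0.1,
    c_max: float = 250.0,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    interferent_uM: float = DEFAULT_INTERFERENT_LEVEL_UM,
    spacing: str = "log",
) -> SpectraSet:
    """Single-analyte standard solutions for every hormone in the library.

    Per hormone: ``levels`` concentrations spanning [c_min, c_max] µM, each
    spectrum = pure analyte + fixed-level interferent + one noise
    realization.  Defaults reproduce the 4 x 65 = 260 standard design over
    0.1-250 µM.  Fully deterministic given ``noise.seed``.
    """
    sigs = _signature_map(signatures or default_signatures())
    grid = grid or WavenumberGrid.default()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    concs = concentration_levels(levels, c_min, c_max, spacing)

    hormones = [n for n in sigs if n != "interferent"]
    spectra: list[Spectrum] = []
    meta: dict[str, SampleMeta] = {}
    for h in hormones:
        clean = np.vstack(
            [_clean_signal({h: c}, sigs, grid, interferent_uM) for c in concs]
        )
        noisy = noise.apply(clean, grid, rng)
        for i, c in enumerate(concs):
            sid = f"std_{h}_{i:03d}"
            spectra.append(Spectrum(grid=grid, absorbance=noisy[i], sample_id=sid))
            meta[sid] = SampleMeta(sample_id=sid, role="standard", analyte=h,
                                   concentration_uM=float(c))
    return SpectraSet(grid=grid, spectra=spectra, meta=meta)


def generate_extracts(
    truth: dict[str, dict[str, float]],
    replicates: int = 3,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    signatures=None,
    interferent_uM: float = DEFAULT_INTERFERENT_LEVEL_UM,
) -> SpectraSet:
    """Multi-hormone "leaf extract" spectra for a population panel.

    ``truth`` maps population -> {hormone: concentration µM}.  Each
    replicate is the Beer-Lambert sum of all hormones plus interferent with
    an independent noise realization.
    """
    sigs = _signature_map(signatures or default_signatures())
    grid = grid or WavenumberGrid.default()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    spectra: list[Spectrum] = []
    meta: dict[str, SampleMeta] = {}
    for pop, conc in truth.items():
        bad = {k: v for k, v in conc.items() if v < 0}
        if bad:
            raise SimulationError(f"{pop}: negative concentrations {bad}")
        clean = _clean_signal(conc, sigs, grid, interferent_uM)
        noisy = noise.apply(np.tile(clean, (replicates, 1)), grid, rng)
        for r in range(replicates):
            sid = f"{pop}_r{r + 1}"
            spectra.append(Spectrum(grid=grid, absorbance=noisy[r], sample_id=sid))
            meta[sid] = SampleMeta(sample_id=sid, role="unknown",
                                   population=pop, replicate=r + 1)
    return SpectraSet(grid=grid, spectra=spectra, meta=meta)
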