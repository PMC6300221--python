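"""Spectral pre-treatments: multiplicative scatter correction (MSC) and
Savitzky-Golay first derivatives, composed with window restriction.

A :class:`PreprocessSpec` names one recipe — the unit over which candidate
calibration models are compared.  The fixed order of operations is
window-first, then transform, so each (window, treatment) pair is a single
self-contained candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_coeffs

from .spectra import SpectraSet, Spectrum, WavenumberGrid, restrict_window

__all__ = [
    "PreprocessSpec",
    "MscFit",
    "msc_fit_reference",
    "msc_correct",
    "sg_first_derivative",
    "apply_preprocess",
    "PreprocessError",
]

METHODS = ("none", "msc", "sg1d")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing recipe: method + wavenumber window + SG parameters.

    method
        ``none`` (window only), ``msc`` (multiplicative scatter correction
        against a mean reference), or ``sg1d`` (Savitzky-Golay smoothed
        first derivative).
    sg_points, sg_polyorder
        SG window length (odd) and fitting polynomial degree; only used by
        ``sg1d``.  13 points / quadratic is the chemometric default.
    """

    method: str = "none"
    window_low: float = 4000.0
    window_high: float = 10000.0
    sg_points: int = 13
    sg_polyorder: int = 2
    label: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise PreprocessError(f"unknown method {self.method!r}")
        if not self.window_low < self.window_high:
            raise PreprocessError("window_low must be < window_high")
        if self.sg_points < 5 or self.sg_points % 2 == 0:
            raise PreprocessError("sg_points must be odd and >= 5")
        if self.sg_polyorder < 1 or self.sg_polyorder >= self.sg_points:
            raise PreprocessError("sg_polyorder must be >= 1 and < sg_points")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.method}[{self.window_low:g}-{self.window_high:g}]",
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**{k: d[k] for k in
                      ("method", "window_low", "window_high",
                       "sg_points", "sg_polyorder", "label") if k in d})


@dataclass
class MscFit:
    """MSC reference spectrum plus the per-sample (offset, slope) fits."""

    reference: np.ndarray
    offsets: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)


def msc_fit_reference(calibration: SpectraSet) -> np.ndarray:
    """Mean calibration spectrum, the MSC reference.

    Frozen into the saved model so external validation and prediction of
    unknowns never refit it.
    """
    if len(calibration) < 2:
        raise PreprocessError("MSC reference needs at least 2 spectra")
    return calibration.as_matrix().mean(axis=0)


def msc_correct(
    spectrum: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Regress a spectrum on the reference; return ((x - a)/b, a, b).

    a and b are the ordinary least-squares intercept and slope of
    ``spectrum ~ a + b * reference``; dividing them out removes additive
    offsets and multiplicative scatter.
    """
    x = np.asarray(spectrum, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.shape != r.shape:
        raise PreprocessError("spectrum and reference lengths differ")
    rc = r - r.mean()
    denom = rc @ rc
    if denom < 1e-30:
        raise PreprocessError("constant MSC reference")
    b = float(rc @ (x - x.mean()) / denom)
    a = float(x.mean() - b * r.mean())
    if abs(b) < 1e-12:
        raise PreprocessError("degenerate MSC fit: |b| < 1e-12")
    return (x - a) / b, a, b


def sg_first_derivative(
    spectrum: Spectrum, sg_points: int = 13, sg_polyorder: int = 2
) -> Spectrum:
    """Savitzky-Golay smoothed d(absorbance)/d(wavenumber).

    Exact on polynomials of degree <= sg_polyorder.  Output drops
    (sg_points-1)/2 points at each edge: only the valid convolution region
    is kept, never padded.
    """
    n = len(spectrum.grid)
    if n < sg_points:
        raise PreprocessError(f"spectrum length {n} < sg_points {sg_points}")
    half = (sg_points - 1) // 2
    step = spectrum.grid.step
    # savgol_coeffs returns filter taps ordered for convolution
    c = savgol_coeffs(sg_points, sg_polyorder, deriv=1, delta=step)
    dy = np.convolve(spectrum.absorbance, c, mode="valid")
    grid = WavenumberGrid(spectrum.grid.values[half : n - half])
    return Spectrum(grid=grid, absorbance=dy, sample_id=spectrum.sample_id)


def apply_preprocess(
    sset: SpectraSet,
    spec: PreprocessSpec,
    msc_reference: np.ndarray | None = None,
) -> tuple[SpectraSet, MscFit | None]:
    """Window-restrict then transform a SpectraSet.

    For ``msc``, the reference is the windowed calibration mean when
    ``msc_reference`` is None (calibration use), or the supplied frozen
    reference (validation / unknown prediction).  Returns the fitted
    :class:`MscFit` for msc, else None.
    """
    windowed = restrict_window(sset, spec.window_low, spec.window_high)
    if spec.method == "none":
        return windowed, None
    if spec.method == "msc":
        ref = msc_fit_reference(windowed) if msc_reference is None else np.asarray(
            msc_reference, dtype=float
        )
        if ref.shape != (len(windowed.grid),):
            raise PreprocessError("MSC reference length != windowed grid length")
        fit = MscFit(reference=ref)
        corrected = []
        for s in windowed.spectra:
            y, a, b = msc_correct(s.absorbance, ref)
            fit.offsets[s.sample_id] = a
            fit.slopes[s.sample_id] = b
            corrected.append(Spectrum(grid=windowed.grid, absorbance=y,
                                      sample_id=s.sample_id))
        return (
            SpectraSet(grid=windowed.grid, spectra=corrected, meta=dict(windowed.meta)),
            fit,
        )
    # sg1d
    out = [sg_first_derivative(s, spec.sg_points, spec.sg_polyorder)
           for s in windowed.spectra]
    grid = out[0].grid if out else WavenumberGrid(
        windowed.grid.values[(spec.sg_points - 1) // 2 : -(spec.sg_points - 1) // 2]
    )
    return SpectraSet(grid=grid, spectra=out, meta=dict(windowed.meta)), None
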