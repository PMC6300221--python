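import numpy as np
import pytest

from phytonirs import (
    SampleMeta,
    SpectraSet,
    Spectrum,
    WavenumberGrid,
    closed_loop,
)
from phytonirs.data import REFERENCE_PROFILES


@pytest.fixture(scope="session")
def small_grid():
    """Short uniform grid for fast unit tests (4000-4200 cm^-1, step 2)."""
    return WavenumberGrid.default(4000, 4200, 2)


def make_set(grid, columns, meta=None):
    """Build a SpectraSet from {sample_id: absorbance array}."""
    spectra = [Spectrum(grid=grid, absorbance=np.asarray(a, float), sample_id=k)
               for k, a in columns.items()]
    if meta is None:
        meta = {k: SampleMeta(sample_id=k, role="unknown", population="X")
                for k in columns}
    return SpectraSet(grid=grid, spectra=spectra, meta=meta)


@pytest.fixture(scope="session")
def truth_profiles():
    """Published per-population hormone contents (µg/g FW) as ground truth."""
    return {p: {h: m for h, (m, _se) in d.items()}
            for p, d in REFERENCE_PROFILES.items()}


@pytest.fixture(scope="session")
def closed_loop_result(truth_profiles):
    """One full closed-loop run (simulate, calibrate, select, predict,
    aggregate) shared by the end-to-end tests."""
    return closed_loop(truth_profiles, seed=1)
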