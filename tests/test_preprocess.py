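import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytonirs import (
    PreprocessSpec,
    Spectrum,
    WavenumberGrid,
    apply_preprocess,
    msc_correct,
    msc_fit_reference,
    sg_first_derivative,
)
from phytonirs.preprocess import PreprocessError

from conftest import make_set


class TestPreprocessSpec:
    @pytest.mark.parametrize("kw", [
        dict(method="bogus"),
        dict(sg_points=12),                 # even
        dict(sg_points=3),                  # too small
        dict(sg_polyorder=0),
        dict(window_low=6000, window_high=4000),
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(PreprocessError):
            PreprocessSpec(**kw)

    def test_serialization_round_trip(self):
        spec = PreprocessSpec(method="sg1d", window_low=4000, window_high=6500,
                              sg_points=13, sg_polyorder=2)
        assert PreprocessSpec.from_dict(spec.to_dict()) == spec


class TestMscReference:
    def test_mean_of_two_spectra(self, small_grid):
        n = len(small_grid)
        sset = make_set(small_grid, {"a": np.full(n, 1.0) + np.arange(n) % 3,
                                     "b": np.full(n, 3.0) + np.arange(n) % 3})
        np.testing.assert_allclose(msc_fit_reference(sset),
                                   2.0 + np.arange(n) % 3)

    def test_copies_of_one_spectrum_give_that_spectrum(self, small_grid):
        x = np.random.default_rng(0).random(len(small_grid))
        sset = make_set(small_grid, {f"c{i}": x.copy() for i in range(4)})
        np.testing.assert_allclose(msc_fit_reference(sset), x)

    def test_matches_columnwise_mean_oracle(self, small_grid):
        rng = np.random.default_rng(3)
        cols = {f"s{i}": rng.random(len(small_grid)) for i in range(5)}
        sset = make_set(small_grid, cols)
        # direct summation oracle
        acc = np.zeros(len(small_grid))
        for v in cols.values():
            acc += v
        np.testing.assert_allclose(msc_fit_reference(sset), acc / 5, rtol=1e-12)

    def test_single_spectrum_rejected(self, small_grid):
        sset = make_set(small_grid, {"only": np.zeros(len(small_grid))})
        with pytest.raises(PreprocessError):
            msc_fit_reference(sset)


class TestMscCorrect:
    def test_self_fit_is_identity(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c, a, b = msc_correct(r, r)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(c, r)

    def test_affine_spectrum_inverts_exactly(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c, a, b = msc_correct(0.5 + 2.0 * r, r)
        assert (a, b) == (pytest.approx(0.5), pytest.approx(2.0))
        np.testing.assert_allclose(c, r, rtol=1e-12)

    def test_against_normal_equations_oracle(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.array([2.1, 4.2, 6.0, 8.1, 10.2])
        # independent OLS via normal equations
        n = r.size
        sb = (n * (r * x).sum() - r.sum() * x.sum()) / (n * (r * r).sum() - r.sum() ** 2)
        sa = (x.sum() - sb * r.sum()) / n
        c, a, b = msc_correct(x, r)
        assert a == pytest.approx(sa, abs=1e-10)
        assert b == pytest.approx(sb, abs=1e-10)
        np.testing.assert_allclose(c, (x - sa) / sb, atol=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(PreprocessError):
            msc_correct(np.arange(5.0), np.ones(5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a0=st.floats(-5, 5), b0=st.floats(0.1, 10), seed=st.integers(0, 100))
    def test_affine_invariance(self, a0, b0, seed):
        """Scaling/offsetting a spectrum does not change its MSC correction."""
        rng = np.random.default_rng(seed)
        r = rng.random(50) + 0.5
        x = rng.random(50)
        c1, _, _ = msc_correct(x, r)
        c2, _, _ = msc_correct(b0 * x + a0, r)
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_idempotence_on_corrected_set(self, small_grid):
        rng = np.random.default_rng(7)
        base = rng.random(len(small_grid)) + 0.5
        # near-affine family: the idempotence identity is exact for affine
        # scatter and degrades only quadratically in the residual
        cols = {f"s{i}": (1 + 0.1 * i) * base + 0.05 * i + 1e-5 * rng.random(len(small_grid))
                for i in range(5)}
        sset = make_set(small_grid, cols)
        spec = PreprocessSpec(method="msc", window_low=4000, window_high=4200)
        corrected, _ = apply_preprocess(sset, spec)
        again, fit = apply_preprocess(corrected, spec)
        for sid in corrected.sample_ids:
            assert abs(fit.offsets[sid]) < 1e-8
            assert abs(fit.slopes[sid] - 1.0) < 1e-8


class TestSgDerivative:
    def test_constant_gives_zero(self, small_grid):
        s = Spectrum(grid=small_grid, absorbance=np.full(len(small_grid), 2.5),
                     sample_id="c")
        d = sg_first_derivative(s, 13, 2)
        np.testing.assert_allclose(d.absorbance, 0.0, atol=1e-12)

    def test_linear_slope_recovered(self, small_grid):
        s = Spectrum(grid=small_grid, absorbance=3.0 * small_grid.values,
                     sample_id="lin")
        d = sg_first_derivative(s, 13, 2)
        np.testing.assert_allclose(d.absorbance, 3.0, rtol=1e-10)
        assert len(d.grid) == len(small_grid) - 12

    def test_exact_on_quadratic(self):
        g = WavenumberGrid.default(4000, 5000, 2)
        v = g.values
        s = Spectrum(grid=g, absorbance=1 + 0.5 * v + 0.01 * v**2, sample_id="q")
        d = sg_first_derivative(s, 13, 2)
        np.testing.assert_allclose(d.absorbance, 0.5 + 0.02 * d.grid.values,
                                   rtol=1e-8)

    def test_too_short_spectrum_rejected(self):
        g = WavenumberGrid(np.arange(4000.0, 4012.0, 2.0))  # 6 points < 13
        s = Spectrum(grid=g, absorbance=np.zeros(6), sample_id="s")
        with pytest.raises(PreprocessError):
            sg_first_derivative(s, 13, 2)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(alpha=st.floats(-3, 3), beta=st.floats(-3, 3), seed=st.integers(0, 50))
    def test_linearity(self, alpha, beta, seed, small_grid):
        rng = np.random.default_rng(seed)
        x = rng.random(len(small_grid))
        y = rng.random(len(small_grid))
        sx = Spectrum(grid=small_grid, absorbance=x, sample_id="x")
        sy = Spectrum(grid=small_grid, absorbance=y, sample_id="y")
        sz = Spectrum(grid=small_grid, absorbance=alpha * x + beta * y,
                      sample_id="z")
        dz = sg_first_derivative(sz, 13, 2).absorbance
        dx = sg_first_derivative(sx, 13, 2).absorbance
        dy = sg_first_derivative(sy, 13, 2).absorbance
        np.testing.assert_allclose(dz, alpha * dx + beta * dy, atol=1e-8)


class TestApplyPreprocess:
    def test_none_with_full_window_is_identity(self, small_grid):
        sset = make_set(small_grid, {"a": np.arange(len(small_grid), dtype=float)})
        out, fit = apply_preprocess(sset, PreprocessSpec())
        assert fit is None
        np.testing.assert_array_equal(out.spectra[0].absorbance,
                                      sset.spectra[0].absorbance)

    def test_sg1d_on_4000_6500_window_drops_twelve_points(self):
        g = WavenumberGrid.default()
        sset = make_set(g, {"a": np.sin(g.values / 500.0)})
        spec = PreprocessSpec(method="sg1d", window_low=4000, window_high=6500)
        out, _ = apply_preprocess(sset, spec)
        assert len(out.grid) == 1251 - 12

    def test_msc_with_stored_reference_is_deterministic(self, small_grid):
        rng = np.random.default_rng(11)
        base = rng.random(len(small_grid)) + 1.0
        cols = {f"s{i}": (1 + 0.05 * i) * base + 0.02 * i for i in range(4)}
        cal = make_set(small_grid, cols)
        spec = PreprocessSpec(method="msc", window_low=4000, window_high=4200)
        out1, fit = apply_preprocess(cal, spec)
        out2, _ = apply_preprocess(make_set(small_grid, cols), spec,
                                   msc_reference=fit.reference)
        for a, b in zip(out1.spectra, out2.spectra):
            np.testing.assert_allclose(a.absorbance, b.absorbance, rtol=1e-12)
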