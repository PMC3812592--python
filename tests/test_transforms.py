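import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from grasspec.spectra_io import SpectralDataset, Spectrum
from grasspec.transforms import (
    TRANSFORM_CODES,
    TransformError,
    TransformPreprocessor,
    apply_transform,
    baseline_offset,
    detrend,
    is_dataset_dependent,
    msc,
    normalize,
    norris_gap_derivative,
    reflectance_to_absorbance,
    snv,
)

WL = np.arange(400.0, 500.0)


def spec(values, wl=WL):
    return Spectrum(wl, np.asarray(values, dtype=float), kind="transformed")


positive_spectra = arrays(
    np.float64,
    WL.size,
    elements=st.floats(0.05, 1.0, allow_nan=False, allow_infinity=False),
)


class TestBaselineOffset:
    def test_constant_to_zeros(self):
        out = baseline_offset(spec(np.full(WL.size, 3.7)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_definition(self):
        out = baseline_offset(spec([1.0, 3.0, 2.0], wl=np.arange(3.0)))
        np.testing.assert_array_equal(out.values, [0.0, 2.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(positive_spectra)
    def test_output_min_is_zero(self, values):
        assert baseline_offset(spec(values)).values.min() == 0.0


class TestDetrend:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_annihilates_degree_k_polynomial(self, k):
        coef = np.arange(1, k + 2, dtype=float)
        values = sum(c * WL**i for i, c in enumerate(coef))
        out = detrend(spec(values / values.max()), k)
        assert np.max(np.abs(out.values)) < 1e-9

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_residuals_orthogonal_to_poly_basis(self, k, rng):
        out = detrend(spec(rng.random(WL.size)), k)
        for i in range(k + 1):
            basis = WL**i
            inner = out.values @ basis / np.linalg.norm(basis)
            assert abs(inner) < 1e-8

    def test_linear_detrend_of_sine(self):
        wl = np.linspace(0.0, 200.0 * np.pi, 4000)
        values = np.sin(wl)
        out = detrend(Spectrum(wl, values, kind="transformed"), 1)
        # over many full periods the least-squares line is nearly zero, and
        # what is removed is exactly a line in wavelength
        removed = values - out.values
        assert np.max(np.abs(removed)) < 0.02
        coef = np.polynomial.polynomial.polyfit(wl, removed, 1)
        line = np.polynomial.polynomial.polyval(wl, coef)
        np.testing.assert_allclose(removed, line, atol=1e-10)

    def test_too_few_bands(self):
        with pytest.raises(TransformError):
            detrend(spec([1.0, 2.0, 3.0], wl=np.arange(3.0)), 3)


class TestMSC:
    def test_identical_spectra_full_is_identity(self):
        row = 0.3 + 0.01 * np.arange(WL.size)
        ds = SpectralDataset(WL, np.vstack([row, row, row]), ("a", "b", "c"))
        out = msc(ds, "full")
        np.testing.assert_allclose(out.matrix, ds.matrix, atol=1e-12)

    def test_full_recovers_reference_from_affine_rows(self):
        shape = 0.3 + 0.1 * np.sin(WL / 15.0)
        rows = np.vstack([a + b * shape for a, b in [(0.1, 2.0), (0.0, 1.0), (-0.05, 0.5)]])
        ds = SpectralDataset(WL, rows, ("a", "b", "c"))
        ref = rows.mean(axis=0)
        out = msc(ds, "full")
        # every corrected row collapses onto the mean reference
        for row in out.matrix:
            np.testing.assert_allclose(row, ref, atol=1e-10)

    def test_closed_form_offset_and_amplification(self):
        shape = 0.3 + 0.1 * np.sin(WL / 15.0)
        x = 2.0 * shape + 0.1
        other = shape.copy()
        ds = SpectralDataset(WL, np.vstack([x, other]), ("a", "b"))
        ref = ds.matrix.mean(axis=0)  # = 1.5*shape + 0.05
        # closed form: x = 0.1/1.5-ish against ref; recompute a, b directly
        b = np.cov(ref, x, ddof=1)[0, 1] / np.var(ref, ddof=1)
        a = x.mean() - b * ref.mean()
        np.testing.assert_allclose(msc(ds, "offset").matrix[0], x - a, atol=1e-12)
        np.testing.assert_allclose(msc(ds, "amplification").matrix[0], x / b, atol=1e-12)
        np.testing.assert_allclose(msc(ds, "full").matrix[0], (x - a) / b, atol=1e-12)

    def test_mean_of_full_output_near_reference(self, rng):
        shape = 0.4 + 0.1 * np.sin(WL / 10.0)
        rows = np.vstack(
            [
                ai + bi * shape + rng.normal(0, 0.002, WL.size)
                for ai, bi in zip(rng.normal(0, 0.05, 8), rng.normal(1, 0.1, 8))
            ]
        )
        ds = SpectralDataset(WL, rows, tuple(f"s{i}" for i in range(8)))
        ref = rows.mean(axis=0)
        out = msc(ds, "full")
        assert np.max(np.abs(out.matrix.mean(axis=0) - ref)) < 0.01

    def test_degenerate_slope_error(self):
        shape = 0.3 + 0.01 * np.arange(WL.size)
        flat = np.full(WL.size, 0.3)  # zero covariance with the reference
        ds = SpectralDataset(WL, np.vstack([shape, 2 * shape, flat]), ("a", "b", "c"))
        with pytest.raises(TransformError):
            msc(ds, "full")

    def test_requires_two_samples(self):
        ds = SpectralDataset(WL, np.random.default_rng(0).random((1, WL.size)), ("a",))
        with pytest.raises(TransformError):
            msc(ds, "full")

    def test_sample_order_invariance(self, rng):
        rows = 0.2 + rng.random((4, WL.size)) * 0.5
        ds = SpectralDataset(WL, rows, ("a", "b", "c", "d"))
        out = msc(ds, "full").matrix
        perm = [2, 0, 3, 1]
        ds_p = SpectralDataset(WL, rows[perm], ("c", "a", "d", "b"))
        out_p = msc(ds_p, "full").matrix
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


class TestNormalize:
    def test_unit_vector_norm_one(self, rng):
        out = normalize(spec(rng.random(WL.size) + 0.1), "unit_vector")
        assert np.linalg.norm(out.values) == pytest.approx(1.0, abs=1e-12)

    def test_max_mode(self, rng):
        out = normalize(spec(rng.random(WL.size) + 0.1), "max")
        assert out.values.max() == pytest.approx(1.0, abs=1e-12)

    def test_area_mode_constant(self):
        wl = np.linspace(0.0, 10.0, 101)
        out = normalize(Spectrum(wl, np.full(101, 2.0), kind="transformed"), "area")
        np.testing.assert_allclose(out.values, 0.1, atol=1e-12)

    def test_mean_and_range_modes(self):
        x = spec([1.0, 2.0, 3.0], wl=np.arange(3.0))
        np.testing.assert_allclose(normalize(x, "mean").values, [0.5, 1.0, 1.5])
        np.testing.assert_allclose(normalize(x, "range").values, [0.5, 1.0, 1.5])

    def test_zero_denominator_error(self):
        with pytest.raises(TransformError):
            normalize(spec(np.zeros(WL.size)), "max")
        with pytest.raises(TransformError):
            normalize(spec(np.ones(WL.size)), "range")


class TestNorrisGapDerivative:
    @pytest.mark.parametrize("g", [3, 5, 7, 9])
    def test_linear_gives_constant_slope(self, g):
        m = 0.0123
        out = norris_gap_derivative(spec(m * WL), g)
        np.testing.assert_allclose(out.values, m, atol=1e-12)
        assert out.n_bands == WL.size - 2 * g

    def test_constant_gives_zeros(self):
        out = norris_gap_derivative(spec(np.full(WL.size, 0.7)), 5)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_exact_on_quadratic(self):
        wl = np.arange(0.0, 50.0)
        out = norris_gap_derivative(Spectrum(wl, wl**2, kind="transformed"), 3)
        np.testing.assert_allclose(out.values, 2.0 * out.wavelengths_nm, atol=1e-10)

    def test_grid_too_short(self):
        with pytest.raises(TransformError):
            norris_gap_derivative(spec(np.zeros(6), wl=np.arange(6.0)), 3)


class TestReflectanceToAbsorbance:
    def test_values(self):
        out = reflectance_to_absorbance(spec([1.0, 0.1], wl=np.arange(2.0)))
        np.testing.assert_allclose(out.values, [0.0, 1.0], atol=1e-12)

    def test_round_trip(self, rng):
        x = rng.random(WL.size) * 0.9 + 0.05
        out = reflectance_to_absorbance(spec(x))
        np.testing.assert_allclose(10.0 ** (-out.values), x, atol=1e-12)

    def test_nonpositive_error(self):
        with pytest.raises(TransformError):
            reflectance_to_absorbance(spec([0.5, 0.0], wl=np.arange(2.0)))


class TestSNV:
    def test_mean_zero_sd_one(self, rng):
        out = snv(spec(rng.random(WL.size)))
        assert abs(out.values.mean()) < 1e-12
        assert out.values.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_triple(self):
        out = snv(spec([0.0, 1.0, 2.0], wl=np.arange(3.0)))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0], atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        positive_spectra,
        st.floats(-0.5, 0.5),
        st.floats(0.1, 5.0),
    )
    def test_affine_invariance(self, values, a, b):
        if np.std(values, ddof=1) < 1e-6:
            return
        base = snv(spec(values)).values
        shifted = snv(spec(a + b * values)).values
        np.testing.assert_allclose(shifted, base, atol=1e-7)

    def test_constant_error(self):
        with pytest.raises(TransformError):
            snv(spec(np.full(WL.size, 0.5)))


class TestDispatch:
    def test_all_codes_run(self, small_dataset):
        for code in TRANSFORM_CODES:
            out = apply_transform(small_dataset, code)
            assert out.n_samples == small_dataset.n_samples

    def test_exactly_18_codes(self):
        assert len(TRANSFORM_CODES) == 18
        assert "CR" not in TRANSFORM_CODES  # continuum removal lives elsewhere

    def test_unknown_code(self, small_dataset):
        with pytest.raises(TransformError):
            apply_transform(small_dataset, "SAVGOL")

    def test_only_msc_is_dataset_dependent(self):
        dependent = {c for c in TRANSFORM_CODES if is_dataset_dependent(c)}
        assert dependent == {"MSCA", "MSCF", "MSCO"}

    def test_ngd_drops_edges(self, small_dataset):
        out = apply_transform(small_dataset, "NGD-7")
        assert out.n_bands == small_dataset.n_bands - 14

    def test_deterministic(self, small_dataset):
        a = apply_transform(small_dataset, "SNV").matrix
        b = apply_transform(small_dataset, "SNV").matrix
        np.testing.assert_array_equal(a, b)


class TestPreprocessor:
    def test_stateless_matches_apply_transform(self, small_dataset):
        pp = TransformPreprocessor("SNV")
        pp.fit(small_dataset.wavelengths_nm, small_dataset.matrix)
        _, out = pp.transform(small_dataset.wavelengths_nm, small_dataset.matrix)
        np.testing.assert_allclose(
            out, apply_transform(small_dataset, "SNV").matrix, atol=1e-12
        )

    def test_msc_reference_comes_from_fit_rows(self, small_dataset):
        X = small_dataset.matrix
        wl = small_dataset.wavelengths_nm
        pp = TransformPreprocessor("MSCF")
        pp.fit(wl, X[:3])
        _, out_train_ref = pp.transform(wl, X[3:])
        pp_full = TransformPreprocessor("MSCF")
        pp_full.fit(wl, X)
        _, out_full_ref = pp_full.transform(wl, X[3:])
        # different references must give different corrections
        assert np.max(np.abs(out_train_ref - out_full_ref)) > 1e-12

    def test_msc_transform_before_fit_errors(self, small_dataset):
        pp = TransformPreprocessor("MSCO")
        with pytest.raises(TransformError):
            pp.transform(small_dataset.wavelengths_nm, small_dataset.matrix)
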