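"""Correction chain stages, optical indices, and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eemsom import (
    AbsorbanceSpectrum,
    ChainConfig,
    CorrectionFunctions,
    apply_spectral_correction,
    fi,
    hix,
    inner_filter_correct,
    max_normalize,
    raman_area,
    raman_normalize,
    run_correction_chain,
    subtract_blank,
    suva,
)

from conftest import make_eem


def flat_spectrum(value, lo=200.0, hi=800.0):
    w = np.array([lo, hi])
    return AbsorbanceSpectrum("abs", w, np.array([value, value]))


class TestSpectralCorrection:
    def test_identity_factors(self, random_eem):
        corr = CorrectionFunctions.identity(
            random_eem.ex_wavelengths, random_eem.em_wavelengths
        )
        out = apply_spectral_correction(random_eem, corr)
        np.testing.assert_array_equal(out.intensity, random_eem.intensity)
        assert out.units_state == "corrected"

    def test_single_row_doubles(self, random_eem):
        fex = np.ones(len(random_eem.ex_wavelengths))
        fex[2] = 2.0
        corr = CorrectionFunctions(
            random_eem.ex_wavelengths, fex,
            random_eem.em_wavelengths, np.ones(len(random_eem.em_wavelengths)),
        )
        out = apply_spectral_correction(random_eem, corr)
        np.testing.assert_allclose(out.intensity[2], 2 * random_eem.intensity[2])
        np.testing.assert_allclose(out.intensity[0], random_eem.intensity[0])

    def test_matches_outer_product_oracle(self, rng, random_eem):
        fex = rng.uniform(0.5, 2.0, len(random_eem.ex_wavelengths))
        fem = rng.uniform(0.5, 2.0, len(random_eem.em_wavelengths))
        corr = CorrectionFunctions(
            random_eem.ex_wavelengths, fex, random_eem.em_wavelengths, fem
        )
        out = apply_spectral_correction(random_eem, corr)
        oracle = np.empty_like(random_eem.intensity)
        for i in range(oracle.shape[0]):
            for j in range(oracle.shape[1]):
                oracle[i, j] = random_eem.intensity[i, j] * fex[i] * fem[j]
        np.testing.assert_allclose(out.intensity, oracle)

    def test_nonpositive_factor_rejected(self, random_eem):
        with pytest.raises(ValueError, match="positive"):
            CorrectionFunctions(
                random_eem.ex_wavelengths,
                np.zeros(len(random_eem.ex_wavelengths)),
                random_eem.em_wavelengths,
                np.ones(len(random_eem.em_wavelengths)),
            )


class TestRaman:
    def test_unit_intensity_window_area(self, flat_unit_eem):
        # width of the 371-428 nm window
        assert raman_area(flat_unit_eem) == pytest.approx(57.0)

    def test_linearity(self, flat_unit_eem):
        doubled = make_eem(
            2 * flat_unit_eem.intensity,
            ex=flat_unit_eem.ex_wavelengths, em=flat_unit_eem.em_wavelengths,
        )
        assert raman_area(doubled) == pytest.approx(114.0)

    def test_triangular_profile_matches_hand_trapezoid(self):
        ex = np.array([349.0, 350.0, 351.0])
        em = np.arange(360.0, 440.0)
        tri = np.maximum(0.0, 1.0 - np.abs(em - 400.0) / 30.0)
        e = make_eem(np.tile(tri, (3, 1)), ex=ex, em=em)
        window = (em >= 371) & (em <= 428)
        hand = sum(
            0.5 * (tri[i] + tri[i + 1])
            for i in range(len(em) - 1)
            if window[i] and window[i + 1]
        )
        assert raman_area(e) == pytest.approx(hand)

    def test_insufficient_coverage_is_hard_error(self):
        e = make_eem(np.ones((3, 5)), ex=[349.0, 350.0, 351.0],
                     em=[380.0, 390.0, 400.0, 410.0, 420.0])
        with pytest.raises(ValueError, match="371"):
            raman_area(e)

    def test_normalise_then_area_is_one(self, flat_unit_eem):
        area = raman_area(flat_unit_eem)
        blank_n = raman_normalize(flat_unit_eem, area)
        assert raman_area(blank_n) == pytest.approx(1.0, abs=1e-12)

    def test_renormalisation_forbidden(self, flat_unit_eem):
        once = raman_normalize(flat_unit_eem, 2.0)
        np.testing.assert_allclose(once.intensity, flat_unit_eem.intensity / 2)
        with pytest.raises(ValueError, match="already"):
            raman_normalize(once, 2.0)


class TestInnerFilter:
    def test_zero_absorbance_identity(self, random_eem):
        out = inner_filter_correct(random_eem, flat_spectrum(0.0))
        np.testing.assert_array_equal(out.intensity, random_eem.intensity)

    def test_unit_absorbance_factor_ten(self, random_eem):
        out = inner_filter_correct(random_eem, flat_spectrum(1.0))
        np.testing.assert_allclose(out.intensity, 10.0 * random_eem.intensity)

    def test_matches_elementwise_oracle(self, rng, random_eem):
        w = np.arange(200.0, 801.0, 50.0)
        a = rng.uniform(0.0, 0.3, len(w))
        spec = AbsorbanceSpectrum("s", w, a, pathlength_cm=2.0)
        out = inner_filter_correct(random_eem, spec)
        for i, ex in enumerate(random_eem.ex_wavelengths):
            for j, em in enumerate(random_eem.em_wavelengths):
                aex = np.interp(ex, w, a) / 2.0
                aem = np.interp(em, w, a) / 2.0
                assert out.intensity[i, j] == pytest.approx(
                    random_eem.intensity[i, j] * 10 ** ((aex + aem) / 2)
                )

    def test_never_decreases_intensity(self, rng, random_eem):
        w = np.arange(200.0, 801.0, 100.0)
        spec = AbsorbanceSpectrum("s", w, rng.uniform(0, 0.5, len(w)))
        out = inner_filter_correct(random_eem, spec)
        assert np.all(out.intensity >= random_eem.intensity)

    def test_negative_absorbance_clipped_with_warning(self, random_eem):
        with pytest.warns(UserWarning, match="clipped"):
            out = inner_filter_correct(random_eem, flat_spectrum(-0.1))
        np.testing.assert_array_equal(out.intensity, random_eem.intensity)

    def test_high_absorbance_warns(self, random_eem):
        with pytest.warns(UserWarning, match="unreliable"):
            inner_filter_correct(random_eem, flat_spectrum(0.9))


class TestBlankSubtraction:
    def test_self_subtraction_zeroes(self, random_eem):
        out = subtract_blank(random_eem, random_eem)
        np.testing.assert_array_equal(out.intensity, np.zeros_like(out.intensity))

    def test_zero_blank_identity(self, random_eem):
        blank = make_eem(np.zeros(random_eem.shape))
        out = subtract_blank(random_eem, blank)
        np.testing.assert_array_equal(out.intensity, random_eem.intensity)

    def test_matches_elementwise_oracle_and_keeps_negatives(self, rng):
        a = make_eem(rng.uniform(0, 1, (3, 4)))
        b = make_eem(rng.uniform(0, 2, (3, 4)))
        out = subtract_blank(a, b)
        np.testing.assert_allclose(out.intensity, a.intensity - b.intensity)
        assert np.any(out.intensity < 0)  # negatives retained

    def test_grid_mismatch_rejected(self, rng):
        a = make_eem(rng.uniform(size=(3, 4)))
        b = make_eem(rng.uniform(size=(3, 4)), ex=[100.0, 110.0, 120.0])
        with pytest.raises(ValueError, match="grid"):
            subtract_blank(a, b)


class TestMaxNormalize:
    def test_max_becomes_one_ratios_kept(self, rng):
        e = make_eem(5.0 * rng.uniform(0.1, 1.0, (4, 4)))
        out = max_normalize(e)
        assert np.nanmax(out.intensity) == pytest.approx(1.0)
        ratio = e.intensity / out.intensity
        np.testing.assert_allclose(ratio, ratio.flat[0])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.1, 2.0, (3, 3))
        out1 = max_normalize(make_eem(base))
        out2 = max_normalize(make_eem(c * base))
        np.testing.assert_allclose(out1.intensity, out2.intensity, rtol=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            max_normalize(make_eem(np.zeros((2, 2))))


class TestIndices:
    def test_hix_flat_is_window_ratio(self, flat_unit_eem):
        # 45-nm over 15-nm emission windows
        assert hix(flat_unit_eem) == pytest.approx(3.0)

    def test_hix_zero_numerator(self, flat_unit_eem):
        intens = np.zeros_like(flat_unit_eem.intensity)
        intens[:, (flat_unit_eem.em_wavelengths >= 330)
               & (flat_unit_eem.em_wavelengths <= 345)] = 1.0
        e = make_eem(intens, ex=flat_unit_eem.ex_wavelengths,
                     em=flat_unit_eem.em_wavelengths)
        assert hix(e) == pytest.approx(0.0)

    def test_hix_piecewise_linear_matches_hand_trapezoid(self):
        ex = np.array([253.0, 254.0, 255.0])
        em = np.arange(320.0, 500.0)
        profile = 0.01 * (em - 320.0)
        e = make_eem(np.tile(profile, (3, 1)), ex=ex, em=em)

        def hand(lo, hi):
            inside = (em >= lo) & (em <= hi)
            w, v = em[inside], profile[inside]
            return np.sum(0.5 * (v[1:] + v[:-1]) * np.diff(w))

        assert hix(e) == pytest.approx(hand(435, 480) / hand(330, 345))

    def test_fi_flat_and_ratio(self, flat_unit_eem):
        assert fi(flat_unit_eem) == pytest.approx(1.0)
        intens = np.ones_like(flat_unit_eem.intensity)
        iex = list(flat_unit_eem.ex_wavelengths).index(370.0)
        jem1 = list(flat_unit_eem.em_wavelengths).index(470.0)
        jem2 = list(flat_unit_eem.em_wavelengths).index(520.0)
        intens[iex, jem1], intens[iex, jem2] = 2.0, 4.0
        e = make_eem(intens, ex=flat_unit_eem.ex_wavelengths,
                     em=flat_unit_eem.em_wavelengths)
        assert fi(e) == pytest.approx(0.5)

    def test_fi_masked_point_missing(self, flat_unit_eem):
        mask = np.ones(flat_unit_eem.shape, dtype=bool)
        iex = list(flat_unit_eem.ex_wavelengths).index(370.0)
        jem = list(flat_unit_eem.em_wavelengths).index(520.0)
        mask[iex, jem - 2 : jem + 3] = False  # mask out the 520 nm region
        e = make_eem(flat_unit_eem.intensity, ex=flat_unit_eem.ex_wavelengths,
                     em=flat_unit_eem.em_wavelengths, mask=mask)
        assert np.isnan(fi(e))

    def test_suva_values(self):
        assert suva(flat_spectrum(0.0), 2.0) == pytest.approx(0.0)
        # ln(10) * 0.1 * 100 / 2
        assert suva(flat_spectrum(0.1), 2.0) == pytest.approx(11.5129, abs=1e-3)
        assert suva(flat_spectrum(0.1), 4.0) == pytest.approx(
            suva(flat_spectrum(0.1), 2.0) / 2
        )

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.floats(0.01, 50.0))
    def test_hix_fi_scale_invariant(self, c):
        rng = np.random.default_rng(3)
        ex = np.arange(250.0, 381.0)
        em = np.arange(300.0, 531.0)
        base = rng.uniform(0.1, 2.0, (len(ex), len(em)))
        e1 = make_eem(base, ex=ex, em=em)
        e2 = make_eem(c * base, ex=ex, em=em)
        assert hix(e1) == pytest.approx(hix(e2), rel=1e-9)
        assert fi(e1) == pytest.approx(fi(e2), rel=1e-9)


class TestChain:
    def test_all_stages_disabled_is_identity(self, flat_unit_eem):
        cfg = ChainConfig(
            spectral_correction=False, raman_normalisation=False,
            inner_filter=False, blank_subtraction=False, max_normalisation=False,
        )
        out, idx = run_correction_chain(flat_unit_eem, config=cfg)
        np.testing.assert_array_equal(out.intensity, flat_unit_eem.intensity)
        assert idx.hix == pytest.approx(3.0)
        assert idx.fi == pytest.approx(1.0)

    def test_chain_equals_manual_composition(self, rng, flat_unit_eem):
        ex, em = flat_unit_eem.ex_wavelengths, flat_unit_eem.em_wavelengths
        sample = make_eem(rng.uniform(1.0, 5.0, flat_unit_eem.shape), ex=ex, em=em)
        blank = make_eem(rng.uniform(0.1, 0.3, flat_unit_eem.shape), ex=ex, em=em)
        corr = CorrectionFunctions(
            ex, rng.uniform(0.9, 1.1, len(ex)), em, rng.uniform(0.9, 1.1, len(em))
        )
        spec = flat_spectrum(0.05)
        out, idx = run_correction_chain(
            sample, blank=blank, corr=corr, abs_spec=spec,
            config=ChainConfig(doc_mg_per_l=2.0),
        )
        s = apply_spectral_correction(sample, corr)
        b = apply_spectral_correction(blank, corr)
        area = raman_area(b)
        s = raman_normalize(s, area)
        b = raman_normalize(b, area)
        s = inner_filter_correct(s, spec)
        s = subtract_blank(s, b)
        manual = max_normalize(s)
        np.testing.assert_allclose(out.intensity, manual.intensity)
        assert idx.raman_area == pytest.approx(area)
        assert idx.suva == pytest.approx(suva(spec, 2.0))
        assert out.units_state == "max_normalised"
        assert "blank_subtraction" in out.provenance
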