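import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryonano import (
    EftemImagePair,
    ScatteringCalibration,
    SyntheticSpec,
    align_pair,
    calibrate_imfp,
    channel_profiles,
    ice_thickness_map,
    make_eftem_pair,
    wet_map,
)
from cryonano.geometry import thickness_profile
from cryonano.thickness import AlignmentUndefinedError


class TestCalibrateImfp:
    def test_sin_film_calibration(self):
        # 19 nm film attenuating the zero-loss signal to 0.89 -> 163 nm IMFP
        assert round(calibrate_imfp(19.0, 0.89)) == 163

    def test_unit_logratio(self):
        assert calibrate_imfp(42.0, np.exp(-1)) == pytest.approx(42.0)

    def test_linearity_in_thickness(self):
        assert calibrate_imfp(38.0, 0.89) == pytest.approx(2 * calibrate_imfp(19.0, 0.89))

    @pytest.mark.parametrize("ratio", [1.0, 1.5, 0.0, -0.2])
    def test_invalid_ratio_raises(self, ratio):
        with pytest.raises(ValueError):
            calibrate_imfp(19.0, ratio)

    @settings(deadline=None, derandomize=True)
    @given(
        t=st.floats(min_value=1.0, max_value=500.0),
        lam=st.floats(min_value=50.0, max_value=1000.0),
    )
    def test_round_trip(self, t, lam):
        assert calibrate_imfp(t, float(np.exp(-t / lam))) == pytest.approx(lam)


class TestAlignPair:
    def _structured(self, rng, shape=(64, 64)):
        base = rng.poisson(1000, shape).astype(float)
        return base + 300 * np.exp(-((np.arange(shape[1]) - 30) ** 2) / 50)[None, :]

    def test_identical_images_zero_shift(self, rng):
        img = self._structured(rng)
        out = align_pair(EftemImagePair(img, img.copy(), pixel_size_A=75.0))
        assert out.shift_px == (0, 0)
        assert out.aligned

    def test_recovers_known_shift(self, rng):
        img = self._structured(rng)
        rolled = np.roll(img, (3, -2), axis=(0, 1))
        out = align_pair(EftemImagePair(img, rolled, pixel_size_A=75.0))
        assert out.shift_px == (-3, 2)  # correction undoing the (3, -2) shift
        interior = np.s_[5:-5, 5:-5]
        assert np.allclose(out.zeroloss_I0[interior], img[interior])
        # shifted-in border marked invalid
        assert not out.valid.all()

    def test_all_zero_image_raises(self):
        z = np.zeros((16, 16))
        with pytest.raises(AlignmentUndefinedError):
            align_pair(EftemImagePair(z, z, pixel_size_A=1.0))


class TestWetMap:
    def test_no_attenuation_gives_zero(self, cal):
        img = np.full((8, 8), 100.0)
        tmap = wet_map(EftemImagePair(img, img.copy(), pixel_size_A=1.0), cal)
        assert np.allclose(tmap.wet_nm, 0.0)

    def test_membrane_ratio_closed_form(self, cal):
        I = np.full((4, 4), 1000.0)
        tmap = wet_map(EftemImagePair(I, 0.89 * I, pixel_size_A=1.0), cal)
        assert np.allclose(tmap.wet_nm, 320 * np.log(1 / 0.89))
        assert tmap.wet_nm[0, 0] == pytest.approx(37.3, abs=0.05)

    def test_negative_pixels_clamped_and_counted(self, cal):
        I = np.full((4, 4), 100.0)
        I0 = I.copy()
        I0[0, 0] = 150.0  # more zero-loss than unfiltered: unphysical pixel
        tmap = wet_map(EftemImagePair(I, I0, pixel_size_A=1.0), cal)
        assert tmap.wet_nm[0, 0] == 0.0
        assert tmap.n_clamped_wet == 1

    def test_zero_count_pixels_masked(self, cal):
        I = np.full((4, 4), 100.0)
        I0 = I * 0.9
        I[1, 1] = 0.0
        tmap = wet_map(EftemImagePair(I, I0, pixel_size_A=1.0), cal)
        assert not tmap.valid[1, 1]
        assert tmap.n_invalid == 1

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=0.999))
    def test_monotone_decreasing_in_ratio(self, ratio):
        cal = ScatteringCalibration()
        I = np.full((2, 2), 1000.0)
        wet_lo = wet_map(EftemImagePair(I, ratio * I, pixel_size_A=1.0), cal).wet_nm[0, 0]
        wet_hi = wet_map(EftemImagePair(I, min(ratio + 1e-3, 1.0) * I, pixel_size_A=1.0), cal).wet_nm[0, 0]
        assert wet_lo > wet_hi

    def test_membrane_stacking_doubles_sin_term(self):
        one = ScatteringCalibration(sin_logratio_ref=0.89)
        two = ScatteringCalibration(sin_logratio_ref=0.89**2)
        assert two.sin_wet_nm == pytest.approx(2 * one.sin_wet_nm)


class TestIceThicknessMap:
    def test_bare_membrane_gives_zero(self, cal):
        I = np.full((4, 4), 1000.0)
        tmap = wet_map(EftemImagePair(I, cal.sin_logratio_ref * I, pixel_size_A=1.0), cal)
        tmap = ice_thickness_map(tmap, cal)
        assert np.allclose(tmap.it_nm, 0.0, atol=1e-9)

    def test_round_trip_recovers_profile(self, clean_spec):
        pair = make_eftem_pair(clean_spec)
        cal = clean_spec.calibration
        tmap = ice_thickness_map(wet_map(pair, cal), cal)
        prof = channel_profiles(tmap, [(0, 64, 0, 129)], n_stripes=5)
        g = clean_spec.geometry
        inside = np.abs(prof.offsets_nm) <= g.width_nm / 2
        expected = thickness_profile(g, prof.offsets_nm[inside])
        assert np.max(np.abs(prof.mean_thickness_nm[inside] - expected)) < 0.5
        assert tmap.it_nm.max() == pytest.approx(100.0, abs=0.5)

    def test_poisson_noise_error_shrinks_with_dose(self):
        cal = ScatteringCalibration()
        rms = []
        for dose in (1e3, 1e4, 1e5):
            spec = SyntheticSpec(seed=7, dose=dose)
            pair = make_eftem_pair(spec)
            tmap = ice_thickness_map(wet_map(pair, cal), cal)
            prof = channel_profiles(tmap, [(0, 64, 0, 129)], n_stripes=5)
            g = spec.geometry
            inside = np.abs(prof.offsets_nm) <= g.width_nm / 2
            resid = prof.mean_thickness_nm[inside] - thickness_profile(g, prof.offsets_nm[inside])
            rms.append(np.sqrt(np.mean(resid**2)))
        assert rms[0] > rms[1] > rms[2]


class TestChannelProfiles:
    def _flat_map(self, value=5.0, shape=(20, 30)):
        from cryonano.thickness import ThicknessMap

        data = np.full(shape, value)
        return ThicknessMap(wet_nm=data, it_nm=data.copy(), pixel_size_A=10.0,
                            valid=np.ones(shape, bool))

    def test_constant_map_flat_profile(self):
        prof = channel_profiles(self._flat_map(), [(0, 20, 0, 30)], n_stripes=5)
        assert np.allclose(prof.mean_thickness_nm, 5.0)
        assert len(prof.per_window_profiles) == 5

    def test_single_stripe_equals_column_mean(self):
        tmap = self._flat_map()
        tmap.it_nm = np.arange(600, dtype=float).reshape(20, 30)
        prof = channel_profiles(tmap, [(0, 20, 0, 30)], n_stripes=1)
        assert np.allclose(prof.mean_thickness_nm, tmap.it_nm.mean(axis=0))

    def test_box_outside_map_raises(self):
        with pytest.raises(IndexError):
            channel_profiles(self._flat_map(), [(0, 25, 0, 30)])
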