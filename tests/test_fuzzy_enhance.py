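import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vetgan import fuzzy_enhance as fe


@pytest.fixture(scope="module")
def fis():
    return fe.default_fis_config()


@pytest.fixture(scope="module")
def lut(fis):
    return fe.build_lut(fis)


class TestMembershipFunctions:
    def test_gaussian_peak_is_one(self):
        mf = fe.gaussian_mf("t", 128, 25)
        assert mf(128) == 1.0

    def test_gaussian_one_sigma_value(self):
        mf = fe.gaussian_mf("t", 100, 25)
        assert mf(125) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_trapezoid_plateau_is_one(self):
        mf = fe.trapezoid_mf("t", 0, 10, 20, 30)
        assert mf(10) == 1.0 and mf(15) == 1.0 and mf(20) == 1.0

    def test_trapezoid_ramps(self):
        mf = fe.trapezoid_mf("t", 0, 10, 20, 30)
        assert mf(5) == pytest.approx(0.5)
        assert mf(25) == pytest.approx(0.5)
        assert mf(35) == 0.0

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            fe.gaussian_mf("t", 0, 0)
        with pytest.raises(ValueError):
            fe.trapezoid_mf("t", 3, 2, 1, 0)

    @given(st.integers(min_value=0, max_value=255))
    @settings(deadline=None, max_examples=64)
    def test_all_degrees_in_unit_interval(self, intensity):
        cfg = fe.default_fis_config()
        degrees = fe.fuzzify(float(intensity), cfg.input_mfs)
        assert (degrees >= 0).all() and (degrees <= 1).all()


class TestRules:
    def test_nothing_fires(self, fis):
        acts = fe.evaluate_rules(
            np.zeros(5), fis.rules, fis.input_terms, fis.output_terms
        )
        assert (acts == 0).all()

    def test_medium_fires_slightly_bright(self, fis):
        m = np.array([0.0, 0.0, 1.0, 0.0, 0.0])  # Medium only
        acts = fe.evaluate_rules(m, fis.rules, fis.input_terms, fis.output_terms)
        by_term = dict(zip(fis.output_terms, acts))
        assert by_term["Slightly Bright"] == 1.0
        assert sum(acts) == 1.0

    def test_max_aggregation_of_shared_consequent(self, fis):
        # Medium and Bright both fire Slightly Bright; max wins
        m = np.array([0.0, 0.0, 0.7, 0.4, 0.0])
        acts = fe.evaluate_rules(m, fis.rules, fis.input_terms, fis.output_terms)
        by_term = dict(zip(fis.output_terms, acts))
        assert by_term["Slightly Bright"] == pytest.approx(0.7)

    def test_unknown_term_is_config_error(self, fis):
        with pytest.raises(ValueError, match="unknown"):
            fe.evaluate_rules(
                np.zeros(5), (("Nope", "No Change"),), fis.input_terms, fis.output_terms
            )


class TestDefuzzify:
    def test_zero_activation_returns_zero(self, fis):
        assert fe.defuzzify(np.zeros(5), fis.output_mfs) == 0.0

    def test_single_symmetric_mf_returns_center(self, fis):
        acts = np.zeros(5)
        acts[list(fis.output_terms).index("Slightly Bright")] = 1.0
        delta = fe.defuzzify(acts, fis.output_mfs, fis.delta_max)
        assert delta == pytest.approx(16.0, abs=0.05)

    def test_symmetric_pair_cancels(self):
        mfs = (fe.trapezoid_mf("neg", -40, -32, -32, -24),
               fe.trapezoid_mf("pos", 24, 32, 32, 40))
        delta = fe.defuzzify(np.array([0.6, 0.6]), mfs, 64.0)
        assert delta == pytest.approx(0.0, abs=1e-9)


class TestLUT:
    def test_length(self, lut):
        assert len(lut) == 256

    def test_matches_unfolded_pipeline(self, fis, lut):
        for i in range(256):
            m = fe.fuzzify(float(i), fis.input_mfs)
            a = fe.evaluate_rules(m, fis.rules, fis.input_terms, fis.output_terms)
            d = fe.defuzzify(a, fis.output_mfs, fis.delta_max, fis.resolution)
            assert lut[i] == int(round(d)), f"mismatch at intensity {i}"

    def test_no_change_on_very_bright_plateau(self, lut):
        # rule 5: saturated pixels are left alone
        assert (lut[223:256] == 0).all()

    def test_mid_gray_brightened_dark_darkened(self, lut):
        assert lut[128] > 0       # Medium -> Slightly Bright
        assert lut[80] < 0        # Dark -> Very Dark
        assert lut[20] < 0        # Very Dark -> Slightly Dark

    def test_deltas_bounded_by_universe(self, fis, lut):
        assert np.abs(lut).max() <= fis.delta_max


class TestEnhanceImage:
    def test_constant_image_single_uniform_shift(self, fis, lut):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        out = fe.enhance_image(img, fis, lut)
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_output_range_and_determinism(self, fis, lut, rng):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        out1 = fe.enhance_image(img, fis, lut)
        out2 = fe.enhance_image(img, fis, lut)
        assert out1.dtype == np.uint8
        assert (out1 == out2).all()

    def test_per_channel_mode_equals_lut_on_each_channel(self, rng):
        fis = fe.default_fis_config(channel_mode="per_channel")
        lut = fe.build_lut(fis)
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        out = fe.enhance_image(img, fis, lut)
        expected = np.clip(img.astype(int) + lut[img], 0, 255)
        assert (out == expected).all()


class TestPSNR:
    def test_identical_images_infinite(self, gradient_image):
        assert fe.psnr(gradient_image, gradient_image) == math.inf

    def test_uniform_error_255_is_zero_db(self):
        a = np.zeros((4, 4, 3))
        b = np.full((4, 4, 3), 255.0)
        assert fe.psnr(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_error_5(self):
        a = np.zeros((4, 4, 3))
        b = np.full((4, 4, 3), 5.0)
        assert fe.psnr(a, b) == pytest.approx(10 * math.log10(255**2 / 25), abs=1e-9)

    def test_symmetry_and_monotonicity(self, rng):
        a = rng.integers(0, 200, size=(8, 8, 3)).astype(float)
        prev = math.inf
        for err in (1, 3, 9, 27):
            b = a + err
            assert fe.psnr(a, b) == fe.psnr(b, a)
            assert fe.psnr(a, b) < prev
            prev = fe.psnr(a, b)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fe.psnr(np.zeros((4, 4, 3)), np.zeros((5, 5, 3)))


def test_comparator_wrappers_run(rng):
    img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
    for f in (fe.clahe_reference, fe.hist_eq_reference):
        out = f(img)
        assert out.shape == img.shape and out.dtype == np.uint8


def test_fis_config_dict_round_trip():
    cfg = fe.default_fis_config(delta_max=48.0, channel_mode="per_channel")
    restored = fe.FISConfig.from_dict(cfg.to_dict())
    assert restored == cfg
    assert (fe.build_lut(restored) == fe.build_lut(cfg)).all()
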