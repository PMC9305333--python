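import numpy as np
import pytest

from mirlight import (
    LuminanceImage,
    RECIPE_NAMES,
    StimulusRecipe,
    detect_x_junctions,
    make_stimulus,
    noised_slc_batch,
    white_stimulus,
)


class TestWhiteStimulus:
    def test_default_palette(self):
        img, spec = white_stimulus()
        assert img.shape == (16, 16)
        assert set(np.unique(img.values)) == {17.5, 35.0, 70.0}

    @pytest.mark.parametrize("frequency,period", [(2, 8), (4, 4), (8, 2)])
    def test_stripe_period(self, frequency, period):
        img, spec = white_stimulus(frequency=frequency)
        col = img.values[:, 0]  # a column without target pixels
        # stripe pattern repeats with the full period
        assert np.array_equal(col, np.roll(col, period))
        assert not np.array_equal(col, np.roll(col, period // 2))
        assert set(np.unique(col)) == {17.5, 70.0}

    def test_left_target_in_dark_right_in_bright(self):
        for f in (2, 4, 8):
            img, spec = white_stimulus(frequency=f)
            half = 16 // (2 * f)
            for (regions, parity) in ((spec.left, 0), (spec.right, 1)):
                rows = {r for r, _ in regions.pixels}
                for r in rows:
                    assert (r // half) % 2 == parity

    def test_targets_mirrored_and_equal_length(self):
        img, spec = white_stimulus()
        mirrored = {(15 - r, 15 - c) for r, c in spec.left.pixels}
        assert mirrored == spec.right.pixels

    def test_degenerate_palette_rejected(self):
        with pytest.raises(ValueError):
            white_stimulus(dark=40.0, bright=40.0)

    def test_vertical_flag_transposes(self):
        h_img, h_spec = white_stimulus()
        v_img, v_spec = white_stimulus(vertical=True)
        assert np.array_equal(v_img.values, h_img.values.T)
        assert {(c, r) for r, c in h_spec.left.pixels} == v_spec.left.pixels


class TestCatalog:
    @pytest.mark.parametrize("name", RECIPE_NAMES)
    def test_every_recipe_builds_valid_stimulus(self, name):
        img, spec = make_stimulus(name)
        assert img.m >= 2 and img.n >= 2
        spec.validate(img)
        left_vals = spec.left.values_in(img.values)
        right_vals = spec.right.values_in(img.values)
        # noise-free figures: targets are luminance-constant and equal
        assert np.all(left_vals == left_vals[0])
        assert np.all(right_vals == right_vals[0])
        assert left_vals[0] == right_vals[0]

    @pytest.mark.parametrize("name", RECIPE_NAMES)
    def test_deterministic(self, name):
        a, sa = make_stimulus(name)
        b, sb = make_stimulus(name)
        assert a == b and sa.left.pixels == sb.left.pixels

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus("not_a_figure")

    def test_slc_targets_on_dark_and_bright_fields(self):
        img, spec = make_stimulus("slc")
        r, c = next(iter(spec.left.pixels))
        assert c < img.n // 2  # left target in the dark half
        r, c = next(iter(spec.right.pixels))
        assert c >= img.n // 2

    def test_scs_control_has_no_sign_invariant_colinear_pair(self):
        img, _ = make_stimulus("scs_control")
        for j in detect_x_junctions(img):
            assert j.vertical_pair_class == "variant"
            assert j.horizontal_pair_class == "variant"

    def test_scs_contains_sign_invariant_junctions(self):
        img, _ = make_stimulus("scs")
        classes = [j.vertical_pair_class for j in detect_x_junctions(img)]
        assert "invariant" in classes

    def test_palette_override(self):
        img, _ = make_stimulus(
            StimulusRecipe("white", palette={"dark": 20.0, "bright": 60.0})
        )
        assert set(np.unique(img.values)) == {20.0, 35.0, 60.0}


class TestNoisedSlcBatch:
    def test_protocol_counts_and_sizes(self):
        batch = noised_slc_batch(seed=3)
        assert len(batch) == 50
        assert all(s.image.shape == (32, 32) for s in batch)
        levels = sorted({s.level for s in batch})
        assert levels == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_targets_physically_identical(self):
        for s in noised_slc_batch(noise_levels=(5.0,), n_per_level=3, seed=9):
            left = s.targets.left.values_in(s.image.values)
            right = s.targets.right.values_in(s.image.values)
            assert np.array_equal(left, right)

    def test_reproducible_from_seed(self):
        a = noised_slc_batch(noise_levels=(2.0,), n_per_level=2, seed=4)
        b = noised_slc_batch(noise_levels=(2.0,), n_per_level=2, seed=4)
        assert all(x.image == y.image for x, y in zip(a, b))

    def test_noise_bounded_by_level(self):
        base, spec = make_stimulus("slc")
        from mirlight import upsample

        up = upsample(base, 2)
        for s in noised_slc_batch(noise_levels=(1.0,), n_per_level=2, seed=5):
            # outside the copied target region the deviation is within +-1
            diff = np.abs(s.image.values - up.values)
            mask = np.ones((32, 32), bool)
            for r, c in s.targets.right.pixels:
                mask[r, c] = False
            assert diff[mask].max() <= 1.0
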