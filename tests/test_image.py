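import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlight import (
    LuminanceImage,
    Region,
    add_uniform_noise,
    copy_region,
    read_luminance_csv,
    upsample,
    write_maps,
)


class TestReadLuminanceCsv:
    def test_parses_matrix_in_row_order(self, tmp_path):
        p = tmp_path / "img.csv"
        p.write_text("10,30\n10,30\n")
        img = read_luminance_csv(p)
        assert img.shape == (2, 2)
        assert np.array_equal(img.values, [[10, 30], [10, 30]])

    @pytest.mark.parametrize(
        "text", ["10,30\n10", "-5,30\n10,30", "10,abc\n10,30", ""]
    )
    def test_rejects_malformed_input(self, tmp_path, text):
        p = tmp_path / "bad.csv"
        p.write_text(text)
        with pytest.raises(ValueError):
            read_luminance_csv(p)


class TestUpsample:
    def test_replicates_pixels_into_blocks(self):
        img = LuminanceImage([[10.0, 30.0]])
        up = upsample(img, 2)
        assert np.array_equal(up.values, [[10, 10, 30, 30], [10, 10, 30, 30]])

    def test_factor_one_is_identity(self):
        img = LuminanceImage([[10.0, 30.0], [5.0, 7.0]])
        assert upsample(img, 1) == img

    @given(a=st.sampled_from([1, 2, 3]), b=st.sampled_from([1, 2, 3]))
    @settings(deadline=None, derandomize=True, max_examples=9)
    def test_composition(self, a, b):
        img = LuminanceImage([[1.0, 2.0], [3.0, 4.0]])
        assert upsample(upsample(img, a), b) == upsample(img, a * b)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            upsample(LuminanceImage([[1.0]]), 0)

    def test_palette_preserved(self):
        img = LuminanceImage([[17.5, 70.0], [35.0, 17.5]])
        up = upsample(img, 3)
        assert set(up.values.ravel()) == set(img.values.ravel())


class TestUniformNoise:
    def test_zero_limit_is_identity(self, rng):
        img = LuminanceImage([[10.0, 30.0], [5.0, 7.0]])
        assert add_uniform_noise(img, 0.0, rng) == img

    def test_bounded_and_unclipped_above_min(self, rng):
        img = LuminanceImage(np.full((20, 20), 35.0))
        out = add_uniform_noise(img, 5.0, rng)
        assert np.all(np.abs(out.values - img.values) <= 5.0)

    def test_clips_at_zero(self, rng):
        img = LuminanceImage(np.full((50, 50), 0.5))
        out = add_uniform_noise(img, 5.0, rng)
        assert out.values.min() == 0.0

    def test_deterministic_given_seed(self):
        img = LuminanceImage(np.full((8, 8), 35.0))
        a = add_uniform_noise(img, 3.0, np.random.default_rng(5))
        b = add_uniform_noise(img, 3.0, np.random.default_rng(5))
        assert a == b

    def test_mean_shift_vanishes_for_many_draws(self):
        img = LuminanceImage(np.full((100, 100), 35.0))
        out = add_uniform_noise(img, 5.0, np.random.default_rng(0))
        assert abs(np.mean(out.values - img.values)) < 5.0 / 5

    def test_rejects_negative_limit(self, rng):
        with pytest.raises(ValueError):
            add_uniform_noise(LuminanceImage([[1.0]]), -1.0, rng)


class TestCopyRegion:
    def test_copies_congruent_region(self, rng):
        img = LuminanceImage(rng.uniform(1, 50, (6, 10)))
        src = Region((1, c) for c in range(1, 9))
        dst = Region((4, c) for c in range(1, 9))
        out = copy_region(img, src, dst)
        assert np.array_equal(src.values_in(out.values), dst.values_in(out.values))
        untouched = np.ones(img.shape, bool)
        for r, c in dst.pixels:
            untouched[r, c] = False
        assert np.array_equal(out.values[untouched], img.values[untouched])

    def test_identity_when_src_equals_dst(self, rng):
        img = LuminanceImage(rng.uniform(1, 50, (4, 4)))
        reg = Region([(1, 1), (1, 2)])
        assert copy_region(img, reg, reg) == img

    def test_rejects_incongruent_or_out_of_bounds(self, rng):
        img = LuminanceImage(rng.uniform(1, 50, (4, 4)))
        with pytest.raises(ValueError):
            copy_region(img, Region([(0, 0), (0, 1)]), Region([(1, 0), (2, 0)]))
        with pytest.raises(ValueError):
            copy_region(img, Region([(0, 0)]), Region([(0, 7)]))


class TestWriteMaps:
    def test_round_trip_and_report(self, tmp_path):
        from mirlight import ModelConfig, best_of_runs
        from mirlight.crf import energy, build_crf

        img = LuminanceImage(np.full((4, 4), 35.0))
        cfg = ModelConfig.preset("modified", runs=2)
        dec = best_of_runs(img, cfg)
        files = write_maps(dec, tmp_path / "out" / "run1")
        refl = read_luminance_csv(tmp_path / "out" / "run1.reflectance.csv")
        assert np.allclose(refl.values, dec.reflectance)
        report = json.loads((tmp_path / "out" / "run1.report.json").read_text())
        g = build_crf(img, cfg)
        assert report["energy"] == pytest.approx(energy(g, dec.assignment))
        assert len(files) == 4
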