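import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mirlight import (
    EdgeClass,
    LuminanceImage,
    PriorWeights,
    classify_edges,
    compute_w1,
    detect_x_junctions,
    michelson_average,
    michelson_total,
)

finite_images = arrays(
    float,
    st.tuples(st.integers(2, 5), st.integers(2, 5)),
    elements=st.floats(0.1, 200.0),
)


class TestMichelson:
    @pytest.mark.parametrize(
        "values,total",
        [
            ([[35.0, 35.0], [35.0, 35.0]], 0.0),
            ([[10.0, 30.0]], 0.5),
            ([[10.0, 30.0], [10.0, 30.0]], 1.0),
        ],
    )
    def test_total_examples(self, values, total):
        assert michelson_total(LuminanceImage(values)) == pytest.approx(total)

    @pytest.mark.parametrize(
        "values,avg",
        [
            ([[35.0, 35.0], [35.0, 35.0]], 0.0),
            ([[10.0, 30.0]], 0.5 / math.sqrt(5)),
            ([[10.0, 30.0], [10.0, 30.0]], 1.0 / math.sqrt(8)),
        ],
    )
    def test_average_examples(self, values, avg):
        assert michelson_average(LuminanceImage(values)) == pytest.approx(avg)

    def test_zero_luminance_pairs_contribute_nothing(self):
        assert michelson_total(LuminanceImage([[0.0, 0.0], [0.0, 0.0]])) == 0.0

    @given(img=finite_images, c=st.floats(0.1, 50.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_scale_invariance(self, img, c):
        a = LuminanceImage(img)
        b = LuminanceImage(c * img)
        assert michelson_total(b) == pytest.approx(michelson_total(a), rel=1e-9)

    @given(img=finite_images)
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_transpose_symmetry(self, img):
        a = LuminanceImage(img)
        b = LuminanceImage(img.T.copy())
        assert michelson_total(b) == pytest.approx(michelson_total(a), rel=1e-9)
        assert michelson_average(b) == pytest.approx(michelson_average(a), rel=1e-9)


class TestAdaptiveW1:
    def test_homogeneous_image_returns_wxvar(self):
        img = LuminanceImage(np.full((16, 16), 35.0))
        assert compute_w1(img) == pytest.approx(50.0)

    def test_two_pixel_example(self):
        img = LuminanceImage([[10.0, 30.0]])
        assert compute_w1(img) == pytest.approx(50 * math.exp(-0.5 / math.sqrt(5)), abs=1e-6)
        assert compute_w1(img) == pytest.approx(39.98, abs=0.01)

    @given(img=finite_images)
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_bounds(self, img):
        w1 = compute_w1(LuminanceImage(img))
        assert 0 < w1 <= 50.0


class TestXJunctions:
    def test_sign_invariant_block(self):
        js = detect_x_junctions(LuminanceImage([[10.0, 50.0], [20.0, 70.0]]))
        assert len(js) == 1
        assert js[0].vertical_pair_class == "invariant"
        assert js[0].horizontal_pair_class == "invariant"

    def test_sign_variant_block(self):
        js = detect_x_junctions(LuminanceImage([[10.0, 50.0], [70.0, 20.0]]))
        assert len(js) == 1
        assert js[0].vertical_pair_class == "variant"

    def test_missing_edge_disqualifies(self):
        assert detect_x_junctions(LuminanceImage([[10.0, 10.0], [20.0, 70.0]])) == []

    @given(img=finite_images)
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_polarity_flip_preserves_classes(self, img):
        a = LuminanceImage(img)
        flipped = LuminanceImage(img.max() + img.min() - img)
        ja = {(j.anchor, j.vertical_pair_class, j.horizontal_pair_class)
              for j in detect_x_junctions(a)}
        jb = {(j.anchor, j.vertical_pair_class, j.horizontal_pair_class)
              for j in detect_x_junctions(flipped)}
        assert ja == jb


class TestClassifyEdges:
    def test_uniform_image_all_equiluminant(self):
        img = LuminanceImage(np.full((4, 4), 35.0))
        cm = classify_edges(img, PriorWeights())
        counts = cm.class_counts()
        assert counts[EdgeClass.EQUILUMINANT] == 24  # all 4-neighbour pairs
        assert all(w == 600.0 for w in cm.weights.values())

    def test_checkerboard_colinear_pairs_all_variant(self):
        v = np.array([[17.5, 70.0] * 2, [70.0, 17.5] * 2] * 2)
        cm = classify_edges(LuminanceImage(v), PriorWeights())
        counts = cm.class_counts()
        assert counts[EdgeClass.X_VARIANT] == 24
        assert counts[EdgeClass.X_INVARIANT] == 0
        assert counts[EdgeClass.PLAIN] == 0

    def test_isolated_step_edge_is_plain_at_w1(self):
        v = np.tile([10.0, 10.0, 70.0, 70.0], (4, 1))
        img = LuminanceImage(v)
        weights = PriorWeights().resolved(img)
        cm = classify_edges(img, weights)
        cls, w = cm[((1, 1), (1, 2))]
        assert cls is EdgeClass.PLAIN
        assert w == pytest.approx(compute_w1(img))

    def test_covers_each_pair_exactly_once(self, rng):
        img = LuminanceImage(rng.uniform(1, 80, (5, 7)))
        cm = classify_edges(img, PriorWeights())
        assert len(cm.classes) == 5 * 6 + 4 * 7

    def test_original_regime_zeroes_all_junction_pairs(self):
        v = np.array([[17.5, 70.0] * 2, [70.0, 17.5] * 2] * 2)
        weights = PriorWeights(w1=20.0, w1_mode="fixed", junction_polarity=False)
        cm = classify_edges(LuminanceImage(v), weights)
        counts = cm.class_counts()
        assert counts[EdgeClass.X_INVARIANT] == 24
        assert all(
            w == 0.0
            for pair, w in cm.weights.items()
            if cm.classes[pair] is EdgeClass.X_INVARIANT
        )

    def test_mirror_stability_of_class_counts(self, rng):
        img = LuminanceImage(rng.uniform(1, 80, (6, 6)))
        cm = classify_edges(img, PriorWeights())
        mirrored = LuminanceImage(img.values[:, ::-1].copy())
        cm2 = classify_edges(mirrored, PriorWeights())
        assert cm.class_counts() == cm2.class_counts()
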