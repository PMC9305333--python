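import dataclasses
import math

import numpy as np
import pytest

from mirlight import LuminanceImage, ModelConfig, best_of_runs, build_crf, energy
from mirlight.crf import IlluminanceLevels, run_inference


class TestUnaryTables:
    def test_feasible_reflectance_has_no_penalty(self, modified_cfg):
        img = LuminanceImage(np.full((2, 2), 35.0))
        g = build_crf(img, modified_cfg)
        lev = modified_cfg.levels.values
        k = int(np.argmin(np.abs(lev - 200.0)))
        r = math.pi * 35.0 / lev[k]
        assert 0.03 < r < 0.9
        expected = (
            modified_cfg.alpha * math.log(lev[k] / lev[0])
            + modified_cfg.anchor_weight * math.log(0.9 / r)
        )
        assert g.unary[0, k] == pytest.approx(expected)

    def test_glow_ramp_above_white_anchor(self, modified_cfg):
        img = LuminanceImage(np.full((2, 2), 70.0))
        g = build_crf(img, modified_cfg)
        lev = modified_cfg.levels.values
        k = int(np.argmin(np.abs(lev - 122.0)))
        r = math.pi * 70.0 / lev[k]
        assert r > 0.9
        expected = modified_cfg.alpha * math.log(lev[k] / lev[0]) + 100.0 * (r - 0.9)
        assert g.unary[0, k] == pytest.approx(expected)

    def test_zero_luminance_pixel_gets_flat_table(self, modified_cfg):
        img = LuminanceImage([[0.0, 35.0], [35.0, 35.0]])
        g = build_crf(img, modified_cfg)
        assert np.all(g.unary[0] == 0.0)


class TestEnergy:
    def test_uniform_assignment_has_no_interaction_terms(self, modified_cfg):
        img = LuminanceImage(np.full((3, 3), 35.0))
        g = build_crf(img, modified_cfg)
        a = np.full((3, 3), 10)
        assert energy(g, a) == pytest.approx(float(g.unary[:, 10].sum()))

    def test_single_step_adds_quadratic_pair_terms(self, modified_cfg):
        img = LuminanceImage(np.full((2, 2), 35.0))
        g = build_crf(img, modified_cfg)
        base = np.full((2, 2), 10)
        stepped = base.copy()
        stepped[:, 1] = 12  # both right pixels two levels up: a straight edge
        d = g.levels.delta
        expected = (
            energy(g, base)
            + float(g.unary[1, 12] + g.unary[3, 12] - g.unary[1, 10] - g.unary[3, 10])
            + 2 * 600.0 * (2 * d) ** 2  # two horizontal equiluminant pairs
        )
        assert energy(g, stepped) == pytest.approx(expected)

    def test_corner_pattern_charged_pass_through_free(self, modified_cfg):
        img = LuminanceImage(np.full((2, 2), 35.0))
        cfg = dataclasses.replace(modified_cfg, w_straight=10.0)
        g = build_crf(img, cfg)
        pass_through = np.array([[10, 12], [10, 12]])
        corner = np.array([[12, 12], [10, 12]])
        d = g.levels.delta
        pair_part = lambda a: float(
            sum(
                g.pair_w[p] * (d * abs(a.ravel()[g.pair_a[p]] - a.ravel()[g.pair_b[p]])) ** 2
                for p in range(g.n_pairs)
            )
        )
        un = lambda a: float(g.unary[np.arange(4), a.ravel()].sum())
        assert energy(g, pass_through) == pytest.approx(un(pass_through) + pair_part(pass_through))
        assert energy(g, corner) == pytest.approx(un(corner) + pair_part(corner) + 10.0)

    def test_incomplete_or_invalid_assignment_rejected(self, modified_cfg):
        img = LuminanceImage(np.full((2, 2), 35.0))
        g = build_crf(img, modified_cfg)
        with pytest.raises(ValueError):
            energy(g, np.zeros((2, 1), int))
        with pytest.raises(ValueError):
            energy(g, np.full((2, 2), 999))


class TestInference:
    def test_deterministic_given_seed(self, modified_cfg):
        img = LuminanceImage([[17.5, 70.0, 17.5], [70.0, 35.0, 70.0]])
        g = build_crf(img, modified_cfg)
        a = run_inference(g, modified_cfg, seed=11)
        b = run_inference(g, modified_cfg, seed=11)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.energy == b.energy

    def test_uniform_image_anchors_at_highest_feasible_reflectance(self, modified_cfg):
        img = LuminanceImage(np.full((4, 4), 35.0))
        cfg = dataclasses.replace(modified_cfg, runs=3)
        dec = best_of_runs(img, cfg)
        assert np.all(dec.illuminance == dec.illuminance[0, 0])
        r = dec.reflectance[0, 0]
        assert r <= 0.9
        # one discrete level lower would overshoot the white anchor
        assert r * math.exp(cfg.levels.delta) > 0.9

    def test_reconstruction_identity(self, modified_cfg, rng):
        img = LuminanceImage(rng.uniform(1, 80, (5, 5)))
        cfg = dataclasses.replace(modified_cfg, runs=2)
        dec = best_of_runs(img, cfg)
        assert np.allclose(
            dec.reflectance * dec.illuminance / math.pi, img.values, rtol=1e-12
        )

    def test_full_link_doubles_message_updates(self, modified_cfg, original_cfg):
        img = LuminanceImage(np.full((4, 5), 35.0))
        full = dataclasses.replace(modified_cfg, iterations=3)
        sweep = dataclasses.replace(
            original_cfg, iterations=3, weights=modified_cfg.weights
        )
        a = run_inference(build_crf(img, full), full, seed=0)
        b = run_inference(build_crf(img, sweep), sweep, seed=0)
        assert a.message_updates == 2 * b.message_updates

    def test_best_of_runs_returns_minimum_energy(self, modified_cfg, rng):
        img = LuminanceImage(rng.uniform(1, 80, (4, 4)))
        cfg = dataclasses.replace(modified_cfg, runs=5, reference_starts=False)
        g = build_crf(img, cfg)
        best = best_of_runs(img, cfg, graph=g)
        singles = [run_inference(g, cfg, cfg.seed + i).energy for i in range(5)]
        assert best.energy == pytest.approx(min(singles))
        assert best.runs_used == 5

    def test_single_run_matches_run_inference(self, modified_cfg, rng):
        img = LuminanceImage(rng.uniform(1, 80, (3, 3)))
        cfg = dataclasses.replace(modified_cfg, runs=1, reference_starts=False)
        g = build_crf(img, cfg)
        assert best_of_runs(img, cfg, graph=g).energy == run_inference(g, cfg, cfg.seed).energy


class TestAgainstExhaustiveOracle:
    def test_map_energy_on_tiny_graphs(self, small_levels, map_oracle, rng):
        hits = 0
        for _ in range(6):
            img = LuminanceImage(rng.uniform(5, 70, (3, 3)))
            cfg = ModelConfig.preset("modified", levels=small_levels, runs=10)
            g = build_crf(img, cfg)
            dec = best_of_runs(img, cfg, graph=g)
            assert dec.energy >= map_oracle(g) - 1e-9
            hits += abs(dec.energy - map_oracle(g)) < 1e-9
        assert hits >= 5

    def test_w_straight_monotonicity(self, small_levels, map_oracle, rng):
        img = LuminanceImage(rng.uniform(5, 70, (2, 3)))
        minima = []
        for ws in (0.0, 5.0, 20.0):
            cfg = ModelConfig.preset("modified", levels=small_levels, w_straight=ws)
            minima.append(map_oracle(build_crf(img, cfg)))
        assert minima == sorted(minima)
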