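"""The illuminance–reflectance conditional random field and its MAP inference.

Each pixel carries a discrete illuminance variable on a log-spaced grid of
lux levels.  Given an input luminance ``x`` (cd/m²) and a candidate
illuminance ``e`` (lux), the implied Lambertian reflectance is
``r = pi * x / e``, so any illuminance labeling determines a reflectance map
exactly (the reconstruction identity).

Energy terms:

* unary — ``alpha * ln(e_k / e_1)`` (lower illuminances are more likely),
  an anchoring pull ``anchor_weight * max(0, ln(r_max / r))`` toward the
  white point, and reflectance feasibility: a linear glow ramp
  ``glow_slope * (r - r_max)`` above the white anchor and a large constant
  below the ``r_min`` floor.
* pairwise — ``w_ij * (ln e_i - ln e_j) ** 2`` for 4-neighbour pairs, with
  ``w_ij`` from :func:`mirlight.contrast.classify_edges`.  The quadratic
  step cost makes moderate, stable illuminance differences optimal rather
  than all-or-nothing jumps; see the methods note.
* straightness — ``w_straight`` for every 2×2 block whose illuminance-edge
  pattern forms a corner (illuminance edges tend to be straight; reflectance
  edges need not be).

MAP inference is damped min-sum loopy belief propagation under a fixed
iteration budget: 3 iterations of the full-link schedule for the modified
model, 6 iterations of the sweep-only schedule for the original regime, the
two being matched in total message count.  Run-to-run variability from the
random message initialization is resolved by keeping the lowest-energy of
``runs`` seeded runs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from . import _bp
from .contrast import PriorWeights, classify_edges
from .image import LuminanceImage

__all__ = [
    "IlluminanceLevels",
    "ModelConfig",
    "FactorGraph",
    "Decomposition",
    "build_crf",
    "energy",
    "run_inference",
    "best_of_runs",
]


@dataclasses.dataclass(frozen=True)
class IlluminanceLevels:
    """Strictly increasing, log-spaced illuminance levels in lux."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape[0] < 2:
            raise ValueError("need at least two illuminance levels")
        if np.any(np.diff(v) <= 0):
            raise ValueError("levels must be strictly increasing")
        steps = np.diff(np.log(v))
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("levels must be log-spaced")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @classmethod
    def log_spaced(cls, K: int = 81, e_min: float = 1.0, e_max: float = 1e4):
        return cls(np.geomspace(e_min, e_max, K))

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def delta(self) -> float:
        """Constant log spacing ln(e_{k+1}/e_k)."""
        return float(math.log(self.values[1] / self.values[0]))


@dataclasses.dataclass
class ModelConfig:
    """All tunable model constants; see docs/methods.md for rationale.

    ``preset("modified")`` / ``preset("original")`` return the two model
    regimes compared throughout the experiments.
    """

    weights: PriorWeights = dataclasses.field(default_factory=PriorWeights)
    levels: IlluminanceLevels = dataclasses.field(
        default_factory=IlluminanceLevels.log_spaced
    )
    alpha: float = 0.1
    #: anchoring prior: cost per log-unit by which a pixel's implied
    #: reflectance falls below the white anchor r_max.  Gives every pixel a
    #: bounded pull toward the illuminance at which it would look white,
    #: implementing the highest-luminance anchoring tendency.
    anchor_weight: float = 0.3
    r_max: float = 0.9
    r_min: float = 0.03
    glow_slope: float = 100.0
    below_floor_cost: float = 1e4
    w_straight: float = 10.0
    pairwise_power: float = 2.0
    damping: float = 0.5
    #: fractional (tree-reweighted style) weight on beliefs when composing
    #: variable-to-factor messages; 1.0 is standard min-sum.
    message_weight: float = 1.0
    #: each run's belief-argmin labeling is polished by this many passes of
    #: monotone region-shift descent on the exact energy (0 disables).
    refine_passes: int = 12
    #: also let two deterministic reference interpretations compete on
    #: energy in best_of_runs: the globally anchored (uniform) one and the
    #: per-pixel anchored (fragmented) one, both refined by the same descent.
    reference_starts: bool = True
    init_noise: float = 0.1
    iterations: int = 3
    runs: int = 30
    schedule: str = "full_link"  # "full_link" | "original"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.iterations < 1 or self.runs < 1:
            raise ValueError("iterations and runs must be >= 1")
        if self.schedule not in ("full_link", "original"):
            raise ValueError("schedule must be 'full_link' or 'original'")
        for name in ("alpha", "glow_slope", "below_floor_cost", "w_straight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.damping < 1):
            raise ValueError("damping must be in [0, 1)")

    @classmethod
    def preset(cls, model: str, **overrides) -> "ModelConfig":
        """The two model regimes.

        ``modified``: full-link schedule, 3 iterations/run, contrast-adaptive
        ``w1``, polarity-aware X-junction weights.  ``original``: sweep-only
        schedule, 6 iterations/run, ``w1`` fixed at 20, zero cost for every
        X-junction colinear pair regardless of polarity.
        """
        if model == "modified":
            cfg = cls(
                weights=PriorWeights(w1_mode="adaptive", junction_polarity=True),
                schedule="full_link",
                iterations=3,
            )
        elif model == "original":
            cfg = cls(
                weights=PriorWeights(w1=20.0, w1_mode="fixed", junction_polarity=False),
                schedule="original",
                iterations=6,
            )
        else:
            raise ValueError("model must be 'modified' or 'original'")
        return dataclasses.replace(cfg, **overrides)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = dataclasses.asdict(self.weights)
        d["levels"] = {
            "K": self.levels.K,
            "e_min": float(self.levels.values[0]),
            "e_max": float(self.levels.values[-1]),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "weights" in d:
            d["weights"] = PriorWeights(**d["weights"])
        if "levels" in d:
            lv = d["levels"]
            d["levels"] = IlluminanceLevels.log_spaced(
                K=lv.get("K", 81), e_min=lv.get("e_min", 1.0), e_max=lv.get("e_max", 1e4)
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class FactorGraph:
    """Array form of the CRF for one image under one configuration."""

    shape: tuple[int, int]
    levels: IlluminanceLevels
    unary: np.ndarray  # (N, K)
    pair_a: np.ndarray  # (P,) flat pixel index, horizontal pairs first
    pair_b: np.ndarray  # (P,)
    pair_w: np.ndarray  # (P,)
    cliques: np.ndarray  # (C, 4) flat pixel indices (TL, TR, BL, BR)
    w_straight: float
    pairwise_power: float
    cfg: ModelConfig
    resolved_weights: PriorWeights
    luminance: np.ndarray  # (m, n) input, kept for the reconstruction identity

    @property
    def n_pairs(self) -> int:
        return self.pair_a.shape[0]

    @property
    def n_cliques(self) -> int:
        return self.cliques.shape[0]

    @property
    def n_variables(self) -> int:
        return self.unary.shape[0]

    def step_costs(self) -> np.ndarray:
        """(K, K) matrix of ``(delta * |i - j|) ** p``."""
        K = self.levels.K
        d = self.levels.delta
        idx = np.arange(K)
        return (d * np.abs(idx[:, None] - idx[None, :])) ** self.pairwise_power


@dataclasses.dataclass
class Decomposition:
    """The model output for one image: what illumination and what surface.

    ``reflectance * illuminance / pi == luminance`` holds exactly for every
    pixel (zero-luminance pixels report reflectance 0).
    """

    illuminance: np.ndarray  # (m, n), lux
    reflectance: np.ndarray  # (m, n), proportion
    glow_mask: np.ndarray  # (m, n), bool: reflectance above the white anchor
    energy: float
    assignment: np.ndarray  # (m, n) level indices
    seed: int
    schedule: str
    iterations: int
    runs_used: int = 1
    message_updates: int = 0


def _unary_table(x: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """(N, K) unary costs.  Zero-luminance pixels get a flat table.

    Three ingredients: a mild preference for lower illuminances
    (``alpha * ln(e/e_1)``), the anchoring pull toward the white point
    (``anchor_weight`` per log-unit of reflectance shortfall below
    ``r_max``), and reflectance feasibility (a glow ramp above ``r_max``, a
    hard floor below ``r_min``).
    """
    e = cfg.levels.values
    base = cfg.alpha * np.log(e / e[0])
    r = math.pi * x.reshape(-1, 1) / e.reshape(1, -1)  # (N, K)
    penalty = np.zeros_like(r)
    over = r > cfg.r_max
    penalty[over] = cfg.glow_slope * (r[over] - cfg.r_max)
    with np.errstate(divide="ignore"):
        shortfall = np.log(cfg.r_max) - np.log(np.where(r > 0, r, 1.0))
    penalty += cfg.anchor_weight * np.maximum(0.0, shortfall)
    penalty[r < cfg.r_min] = cfg.below_floor_cost
    table = base.reshape(1, -1) + penalty
    table[x.reshape(-1) == 0.0, :] = 0.0
    return table


def build_crf(img: LuminanceImage, cfg: ModelConfig) -> FactorGraph:
    """Assemble unary tables, edge-classified pairwise weights and 2×2 cliques."""
    if img.m < 2 or img.n < 2:
        raise ValueError("model requires at least a 2x2 image")
    weights = cfg.weights.resolved(img)
    cost_map = classify_edges(img, weights)
    m, n = img.shape
    flat = lambda r, c: r * n + c
    pa, pb, pw = [], [], []
    for r in range(m):  # horizontal pairs, row-major
        for c in range(n - 1):
            pa.append(flat(r, c))
            pb.append(flat(r, c + 1))
            pw.append(cost_map.weights[((r, c), (r, c + 1))])
    for r in range(m - 1):  # vertical pairs, row-major
        for c in range(n):
            pa.append(flat(r, c))
            pb.append(flat(r + 1, c))
            pw.append(cost_map.weights[((r, c), (r + 1, c))])
    cliques = [
        [flat(r, c), flat(r, c + 1), flat(r + 1, c), flat(r + 1, c + 1)]
        for r in range(m - 1)
        for c in range(n - 1)
    ]
    return FactorGraph(
        shape=(m, n),
        levels=cfg.levels,
        unary=_unary_table(img.values, cfg),
        pair_a=np.array(pa, dtype=np.int64),
        pair_b=np.array(pb, dtype=np.int64),
        pair_w=np.array(pw, dtype=float),
        cliques=np.array(cliques, dtype=np.int64).reshape(-1, 4),
        w_straight=cfg.w_straight,
        pairwise_power=cfg.pairwise_power,
        cfg=cfg,
        resolved_weights=weights,
        luminance=img.values,
    )


def _clique_cost(ka: int, kb: int, kc: int, kd: int, w_s: float) -> float:
    """Straightness cost of one 2×2 block given its four level indices.

    Edge pattern over (top, bottom, left, right); free when empty, a straight
    pass-through (two opposite edges) or a full crossing (four edges); every
    corner-forming pattern (two adjacent edges, or three edges) costs w_s.
    """
    top = bool(ka != kb)
    bottom = bool(kc != kd)
    left = bool(ka != kc)
    right = bool(kb != kd)
    cnt = int(top) + int(bottom) + int(left) + int(right)
    if cnt == 0 or cnt == 4:
        return 0.0
    if cnt == 2 and ((top and bottom) or (left and right)):
        return 0.0
    return w_s


def energy(graph: FactorGraph, assignment: np.ndarray) -> float:
    """Exact energy of a complete labeling (level indices, shape m×n)."""
    m, n = graph.shape
    a = np.asarray(assignment)
    if a.shape != (m, n):
        raise ValueError(f"assignment shape {a.shape} != image shape {(m, n)}")
    flat = a.reshape(-1)
    if flat.min() < 0 or flat.max() >= graph.levels.K:
        raise ValueError("assignment contains out-of-range level indices")
    total = float(graph.unary[np.arange(flat.shape[0]), flat].sum())
    d = graph.levels.delta
    diffs = np.abs(flat[graph.pair_a] - flat[graph.pair_b])
    total += float((graph.pair_w * (d * diffs) ** graph.pairwise_power).sum())
    for tl, tr, bl, br in graph.cliques:
        total += _clique_cost(flat[tl], flat[tr], flat[bl], flat[br], graph.w_straight)
    return total


def run_inference(graph: FactorGraph, cfg: ModelConfig, seed: int) -> Decomposition:
    """One BP run: seeded message init, fixed iteration budget, exact energy.

    Deterministic given (graph, cfg, seed).  Belief argmin ties break toward
    the lower level index (the lower illuminance).
    """
    rng = np.random.default_rng(seed)
    m, n = graph.shape
    P, C, K = graph.n_pairs, graph.n_cliques, graph.levels.K
    pmsg = rng.uniform(0.0, cfg.init_noise, size=(P, 2, K))
    cmsg = rng.uniform(0.0, cfg.init_noise, size=(C, 4, K))
    full_link = cfg.schedule == "full_link"
    n_links = 2 * P + 4 * C
    if full_link:
        orders = np.stack(
            [rng.permutation(n_links) for _ in range(cfg.iterations)]
        ).astype(np.int64)
    else:
        orders = np.zeros((1, 0), dtype=np.int64)
    belief, count = _bp.run_bp(
        graph.unary,
        graph.pair_a,
        graph.pair_b,
        graph.pair_w,
        graph.step_costs(),
        graph.cliques,
        float(graph.w_straight),
        m,
        n,
        pmsg,
        cmsg,
        orders,
        cfg.iterations,
        full_link,
        float(cfg.damping),
        float(cfg.message_weight),
        float(graph.pairwise_power),
        float(graph.levels.delta),
    )
    assignment = np.argmin(belief, axis=1).astype(np.int64)
    if cfg.refine_passes > 0:
        _bp.refine_assignment(
            assignment,
            graph.unary,
            graph.pair_a,
            graph.pair_b,
            graph.pair_w,
            graph.levels.delta,
            graph.pairwise_power,
            graph.cliques,
            float(graph.w_straight),
            m,
            n,
            K,
            cfg.refine_passes,
        )
    assignment = assignment.reshape(m, n)
    e_map = graph.levels.values[assignment]
    refl = math.pi * graph.luminance / e_map
    refl[graph.luminance == 0.0] = 0.0
    return Decomposition(
        illuminance=e_map,
        reflectance=refl,
        glow_mask=refl > cfg.r_max,
        energy=energy(graph, assignment),
        assignment=assignment,
        seed=seed,
        schedule=cfg.schedule,
        iterations=cfg.iterations,
        runs_used=1,
        message_updates=int(count),
    )


def _decomposition_from_assignment(
    graph: FactorGraph, cfg: ModelConfig, assignment: np.ndarray, seed: int
) -> Decomposition:
    m, n = graph.shape
    assignment = assignment.reshape(m, n)
    e_map = graph.levels.values[assignment]
    refl = math.pi * graph.luminance / e_map
    refl[graph.luminance == 0.0] = 0.0
    return Decomposition(
        illuminance=e_map,
        reflectance=refl,
        glow_mask=refl > cfg.r_max,
        energy=energy(graph, assignment),
        assignment=assignment,
        seed=seed,
        schedule=cfg.schedule,
        iterations=cfg.iterations,
    )


def _reference_candidates(graph: FactorGraph, cfg: ModelConfig) -> list[Decomposition]:
    """Two deterministic descent-only interpretations.

    The globally anchored start places every pixel at the lowest level that
    keeps the image maximum within the white anchor (the uniform
    highest-luminance-rule reading); the fragmented start places every pixel
    at its own unary optimum.  Both are then polished by the same monotone
    region-shift descent used on BP labelings, so structured optima are
    reachable from either side regardless of message-passing luck.
    """
    K = graph.levels.K
    x_max = float(graph.luminance.max())
    if x_max > 0:
        k_anchor = int(np.searchsorted(graph.levels.values, math.pi * x_max / cfg.r_max))
        k_anchor = min(max(k_anchor, 0), K - 1)
    else:
        k_anchor = 0
    starts = [
        np.full(graph.n_variables, k_anchor, dtype=np.int64),
        np.argmin(graph.unary, axis=1).astype(np.int64),
    ]
    out = []
    for a in starts:
        if cfg.refine_passes > 0:
            _bp.refine_assignment(
                a, graph.unary, graph.pair_a, graph.pair_b, graph.pair_w,
                graph.levels.delta, graph.pairwise_power, graph.cliques,
                float(graph.w_straight), graph.shape[0], graph.shape[1], K,
                cfg.refine_passes,
            )
        out.append(_decomposition_from_assignment(graph, cfg, a, cfg.seed))
    return out


def best_of_runs(
    img: LuminanceImage, cfg: ModelConfig, graph: FactorGraph | None = None
) -> Decomposition:
    """Lowest-energy decomposition over ``cfg.runs`` seeded BP runs.

    Runs use seeds ``cfg.seed, cfg.seed + 1, ...``; ties keep the earliest
    run.  The run manager exists because short fixed-budget BP shows minor
    random fluctuations between runs.  With ``cfg.reference_starts`` the two
    deterministic reference interpretations also compete on energy.
    """
    if graph is None:
        graph = build_crf(img, cfg)
    best: Decomposition | None = None
    for i in range(cfg.runs):
        dec = run_inference(graph, cfg, cfg.seed + i)
        if best is None or dec.energy < best.energy:
            best = dec
    if cfg.reference_starts:
        for dec in _reference_candidates(graph, cfg):
            if dec.energy < best.energy:
                best = dec
    assert best is not None
    best.runs_used = cfg.runs
    return best
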