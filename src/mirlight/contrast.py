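"""Contrast statistics and X-junction priors for illuminance-edge costs.

Two image-driven priors control how willing the model is to place an
illuminance change between two adjacent pixels:

* A global one: images with more total luminance contrast are expected to
  contain more illumination changes, so the cost ``w1`` charged at a plain
  luminance edge decreases with the image's average Michelson contrast,
  ``w1 = wXvar * exp(-MC_average)``.

* A local one: an X-junction (a 2×2 block in which all four adjacent pixel
  pairs differ) is a classic transparency/shadow cue, but only when its two
  colinear edges have the *same* contrast polarity (sign-invariant).  Those
  pairs get cost ``wXinv`` (0 by default: an illumination boundary is free),
  while opposite-polarity (sign-variant) colinear pairs — typical of pure
  reflectance patterns such as checkerboards — get the high cost ``wXvar``.

Equiluminant pairs keep a large constant cost ``w0``: illumination virtually
never changes between two pixels of identical luminance.
"""

from __future__ import annotations

import dataclasses
import math
from enum import Enum

import numpy as np

from .image import LuminanceImage

__all__ = [
    "PriorWeights",
    "XJunction",
    "EdgeClass",
    "EdgeCostMap",
    "michelson_total",
    "michelson_average",
    "compute_w1",
    "detect_x_junctions",
    "classify_edges",
]

#: Absolute tolerance for "equiluminant".  Stimulus palettes are exact floats
#: and additive noise makes exact ties measure-zero, so this only guards
#: against floating-point round-off.
EQUAL_TOL = 1e-9


@dataclasses.dataclass
class PriorWeights:
    """Illuminance-change costs per adjacent-pixel-pair class.

    ``w1`` is the cost at a plain luminance edge; with ``w1_mode="adaptive"``
    it is derived from the image contrast at model-build time, with
    ``w1_mode="fixed"`` the stored value is used as-is (the original-model
    regime holds it at 20).
    """

    w0: float = 600.0
    wXinv: float = 0.0
    wXvar: float = 50.0
    w1: float = 20.0
    w1_mode: str = "adaptive"  # "adaptive" | "fixed"
    #: original-model regime: every X-junction colinear pair costs 0
    #: regardless of contrast polarity.
    junction_polarity: bool = True

    def __post_init__(self) -> None:
        for name in ("w0", "wXinv", "wXvar", "w1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w1_mode not in ("adaptive", "fixed"):
            raise ValueError("w1_mode must be 'adaptive' or 'fixed'")

    def resolved(self, img: LuminanceImage) -> "PriorWeights":
        """Return a copy with ``w1`` resolved for ``img`` (no-op when fixed)."""
        if self.w1_mode == "fixed":
            return dataclasses.replace(self)
        return dataclasses.replace(self, w1=compute_w1(img, self), w1_mode="fixed")


class EdgeClass(str, Enum):
    EQUILUMINANT = "equiluminant"
    PLAIN = "plain"
    X_INVARIANT = "x_invariant"
    X_VARIANT = "x_variant"


@dataclasses.dataclass(frozen=True)
class XJunction:
    """A qualifying 2×2 block, anchored at its top-left pixel.

    ``vertical_pair_class`` describes the two vertical colinear edges (the
    luminance steps between horizontally aligned pixels), ``horizontal_pair_class``
    the two horizontal edges.
    """

    anchor: tuple[int, int]
    vertical_pair_class: str  # "invariant" | "variant"
    horizontal_pair_class: str


@dataclasses.dataclass
class EdgeCostMap:
    """Class and weight for every 4-neighbour pixel pair of an image.

    Keys are ``((r1, c1), (r2, c2))`` with the first coordinate lexicographically
    smaller; each adjacent pair of the image appears exactly once.
    """

    classes: dict[tuple[tuple[int, int], tuple[int, int]], EdgeClass]
    weights: dict[tuple[tuple[int, int], tuple[int, int]], float]

    def __getitem__(self, pair):
        pair = tuple(sorted(pair))
        return self.classes[pair], self.weights[pair]

    def class_counts(self) -> dict[EdgeClass, int]:
        counts = {cls: 0 for cls in EdgeClass}
        for cls in self.classes.values():
            counts[cls] += 1
        return counts


def _pair_contrasts(img: LuminanceImage) -> np.ndarray:
    """Michelson contrast of every 4-neighbour pair, as a flat array.

    A pair of two zero-luminance pixels has an undefined ratio 0/0 and
    contributes 0 (it is equiluminant, not a contrast).
    """
    v = img.values
    out = []
    for a, b in ((v[:, :-1], v[:, 1:]), (v[:-1, :], v[1:, :])):
        s = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            mc = np.abs(a - b) / s
        mc = np.where(s > 0, mc, 0.0)
        out.append(mc.ravel())
    return np.concatenate(out) if out else np.zeros(0)


def michelson_total(img: LuminanceImage) -> float:
    """Sum of |l1−l2|/(l1+l2) over all 4-neighbour pixel pairs."""
    return float(_pair_contrasts(img).sum())


def michelson_average(img: LuminanceImage) -> float:
    """``michelson_total`` normalized by the image diagonal √(m²+n²).

    The diagonal normalization makes the statistic approximately invariant
    under pixel-replication upsampling, unlike per-pair or per-pixel means.
    """
    return michelson_total(img) / math.hypot(img.m, img.n)


def compute_w1(img: LuminanceImage, weights: PriorWeights | None = None) -> float:
    """Adaptive plain-edge cost ``wXvar * exp(-MC_average)``.

    Equals ``wXvar`` (50 by default) for a zero-contrast image and decays
    toward — but never reaches — zero as image contrast grows, so
    ``0 < w1 <= wXvar``.
    """
    if weights is None:
        weights = PriorWeights()
    return float(weights.wXvar * math.exp(-michelson_average(img)))


def detect_x_junctions(img: LuminanceImage) -> list[XJunction]:
    """All qualifying 2×2 blocks with their colinear-pair polarity classes.

    A block qualifies as an X-junction iff all four within-block adjacent
    pairs have a nonzero luminance difference (two luminance edges actually
    cross).  The vertical colinear pair is sign-invariant iff
    ``sign(TR−TL) == sign(BR−BL)``; the horizontal pair iff
    ``sign(BL−TL) == sign(BR−TR)``.
    """
    v = img.values
    out: list[XJunction] = []
    for r in range(img.m - 1):
        for c in range(img.n - 1):
            tl, tr = v[r, c], v[r, c + 1]
            bl, br = v[r + 1, c], v[r + 1, c + 1]
            d_top, d_bottom = tr - tl, br - bl
            d_left, d_right = bl - tl, br - tr
            if (
                abs(d_top) <= EQUAL_TOL
                or abs(d_bottom) <= EQUAL_TOL
                or abs(d_left) <= EQUAL_TOL
                or abs(d_right) <= EQUAL_TOL
            ):
                continue
            vert = "invariant" if (d_top > 0) == (d_bottom > 0) else "variant"
            horiz = "invariant" if (d_left > 0) == (d_right > 0) else "variant"
            out.append(XJunction((r, c), vert, horiz))
    return out


def classify_edges(img: LuminanceImage, weights: PriorWeights) -> EdgeCostMap:
    """Assign a class and illuminance-change cost to every adjacent pair.

    Equal luminances → ``(equiluminant, w0)``.  A pair that is a colinear
    member of at least one X-junction takes the junction weight: invariant in
    any containing junction wins over variant (the original model zeroed the
    cost for *any* junction membership; evidence for an illumination edge
    anywhere suffices).  Everything else is a plain edge at ``w1``.

    With ``junction_polarity=False`` (original-model regime) every junction
    colinear pair costs ``wXinv`` regardless of polarity.
    """
    if weights.w1_mode == "adaptive":
        weights = weights.resolved(img)
    v = img.values
    classes: dict = {}
    weights_map: dict = {}

    # baseline: equiluminant vs plain
    for r in range(img.m):
        for c in range(img.n):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= img.m or c2 >= img.n:
                    continue
                pair = ((r, c), (r2, c2))
                if abs(v[r, c] - v[r2, c2]) <= EQUAL_TOL:
                    classes[pair] = EdgeClass.EQUILUMINANT
                    weights_map[pair] = weights.w0
                else:
                    classes[pair] = EdgeClass.PLAIN
                    weights_map[pair] = weights.w1

    # junction overrides; invariant dominates variant dominates plain
    rank = {EdgeClass.PLAIN: 0, EdgeClass.X_VARIANT: 1, EdgeClass.X_INVARIANT: 2}
    for xj in detect_x_junctions(img):
        r, c = xj.anchor
        vert_cls = (
            EdgeClass.X_INVARIANT
            if (not weights.junction_polarity or xj.vertical_pair_class == "invariant")
            else EdgeClass.X_VARIANT
        )
        horiz_cls = (
            EdgeClass.X_INVARIANT
            if (not weights.junction_polarity or xj.horizontal_pair_class == "invariant")
            else EdgeClass.X_VARIANT
        )
        # vertical colinear edges are the two horizontal-neighbour pairs
        for pair, cls in (
            (((r, c), (r, c + 1)), vert_cls),
            (((r + 1, c), (r + 1, c + 1)), vert_cls),
            (((r, c), (r + 1, c)), horiz_cls),
            (((r, c + 1), (r + 1, c + 1)), horiz_cls),
        ):
            if rank[cls] > rank[classes[pair]]:
                classes[pair] = cls
                weights_map[pair] = (
                    weights.wXinv if cls is EdgeClass.X_INVARIANT else weights.wXvar
                )
    return EdgeCostMap(classes, weights_map)
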