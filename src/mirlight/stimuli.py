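"""Parametric generators for the lightness-illusion test figures.

Every generator returns a :class:`~mirlight.image.LuminanceImage` together
with a :class:`TargetSpec` naming two pixel sets ("left" and "right") over
which the illusion magnitude (mean predicted reflectance, left minus right)
is evaluated.

The figures are reconstructed on small canvases (16×16 unless noted) with
documented default palettes.  Only the White's-effect palette (stripes 17.5
and 70 cd/m², targets 35 cd/m²) is a published value; every other palette is
a configurable default chosen to preserve the defining ordinal structure of
its figure (which surfaces are darker/lighter, where contrast polarities in
X-junctions do or do not flip).  Externally supplied stimulus matrices can
always be used instead via :func:`mirlight.image.read_luminance_csv`.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .image import LuminanceImage, Region, add_uniform_noise, copy_region, upsample

__all__ = [
    "TargetSpec",
    "StimulusRecipe",
    "NoisedStimulus",
    "white_stimulus",
    "make_stimulus",
    "noised_slc_batch",
    "RECIPE_NAMES",
]


@dataclasses.dataclass(frozen=True)
class TargetSpec:
    """The two labeled target regions of an illusion figure."""

    left: Region
    right: Region

    def __post_init__(self) -> None:
        if self.left.pixels & self.right.pixels:
            raise ValueError("left and right target regions must be disjoint")

    def validate(self, img: LuminanceImage) -> None:
        self.left.validate(img)
        self.right.validate(img)

    def upsampled(self, factor: int) -> "TargetSpec":
        return TargetSpec(self.left.upsampled(factor), self.right.upsampled(factor))

    def transposed(self) -> "TargetSpec":
        flip = lambda reg: Region((c, r) for r, c in reg.pixels)
        return TargetSpec(flip(self.left), flip(self.right))


@dataclasses.dataclass
class StimulusRecipe:
    """A named figure plus its geometry and palette overrides."""

    name: str
    size: int = 16
    params: dict = dataclasses.field(default_factory=dict)
    palette: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class NoisedStimulus:
    level: float
    index: int
    image: LuminanceImage
    targets: TargetSpec


# ---------------------------------------------------------------------------
# White's effect and variants
# ---------------------------------------------------------------------------


def _stripe_of(row: int, half_period: int) -> int:
    return row // half_period


def white_stimulus(
    size: int = 16,
    frequency: int = 4,
    dark: float = 17.5,
    bright: float = 70.0,
    target: float = 35.0,
    target_len: int = 8,
    target_width: int = 1,
    vertical: bool = False,
) -> tuple[LuminanceImage, TargetSpec]:
    """Square-wave stripe figure with two embedded gray target bars.

    Horizontal stripes alternate ``dark``/``bright`` with ``frequency``
    cycles per image.  One bar sits in a dark stripe (the "left" target), the
    other in a bright stripe at the point-mirrored position.  With
    ``target_width`` larger than the stripe width the bars deliberately span
    several stripes (the tall-target variant).  ``vertical=True`` transposes
    the figure.
    """
    if frequency < 1 or size % (2 * frequency) != 0:
        raise ValueError("frequency must divide size/2 (integral stripe width)")
    if dark >= bright:
        raise ValueError("stripe luminances must satisfy dark < bright")
    if min(dark, bright, target) < 0:
        raise ValueError("luminances must be >= 0")
    half = size // (2 * frequency)  # stripe width in px
    if not (1 <= target_len <= size):
        raise ValueError("target_len outside canvas")
    if not (1 <= target_width <= size // 2):
        raise ValueError("target_width outside canvas")

    values = np.empty((size, size), dtype=float)
    for r in range(size):
        values[r, :] = dark if _stripe_of(r, half) % 2 == 0 else bright

    # dark stripe in the upper half closest to the image centre; the point
    # mirror maps it onto a bright stripe in the lower half, keeping the two
    # bars well separated.
    centre = (size - 1) / 2
    dark_stripes = [
        s for s in range(2 * frequency)
        if s % 2 == 0 and s * half + (half - 1) / 2 < centre
    ]
    s_star = min(dark_stripes, key=lambda s: (abs(s * half + (half - 1) / 2 - centre), s))
    lr0 = s_star * half + (half - target_width) // 2
    lr0 = max(0, min(size - target_width, lr0))
    lc0 = (size - target_len) // 2
    left = Region(
        (lr0 + dr, lc0 + c) for dr in range(target_width) for c in range(target_len)
    )
    right = Region((size - 1 - r, size - 1 - c) for r, c in left.pixels)
    if left.pixels & right.pixels:
        raise ValueError("target geometry overflows: mirrored bars collide")
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    img = LuminanceImage(values)
    spec = TargetSpec(left, right)
    if vertical:
        img = LuminanceImage(values.T.copy())
        spec = spec.transposed()
    spec.validate(img)
    return img, spec


def _howe_control(size: int, dark: float, bright: float, target: float,
                  target_len: int) -> tuple[LuminanceImage, TargetSpec]:
    """White-like figure in which both bars straddle a dark|bright boundary.

    The two targets have congruent surrounds (dark stripe above, bright
    below), the configuration reported to abolish the illusion.
    """
    half = size // 8  # 4 cycles/image
    values = np.empty((size, size), dtype=float)
    for r in range(size):
        values[r, :] = dark if _stripe_of(r, half) % 2 == 0 else bright
    lc0 = (size - target_len) // 2
    lr0 = 2 * half - 1  # last row of dark stripe 1 -> straddles into stripe 2
    left = Region((lr0 + dr, lc0 + c) for dr in range(2) for c in range(target_len))
    right = Region((size - 1 - r, size - 1 - c) for r, c in left.pixels)
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    img = LuminanceImage(values)
    return img, TargetSpec(left, right)


# ---------------------------------------------------------------------------
# simultaneous lightness contrast
# ---------------------------------------------------------------------------


def _slc(size: int, field_dark: float, field_bright: float, target: float,
         articulated: bool, dark_set=None, bright_set=None):
    values = np.empty((size, size), dtype=float)
    h = size // 2
    values[:, :h] = field_dark
    values[:, h:] = field_bright
    if articulated:
        dark_set = list(dark_set or (4.0, 8.0, 12.0, 16.0))
        bright_set = list(bright_set or (55.0, 65.0, 75.0, 85.0))
        patch = 2
        for pr in range(size // patch):
            for pc in range(size // patch):
                vals = dark_set if pc < h // patch else bright_set
                v = vals[(pr + 2 * pc) % len(vals)]
                values[pr * patch:(pr + 1) * patch, pc * patch:(pc + 1) * patch] = v
    tr0 = size // 2 - 1
    left = Region((tr0 + dr, h // 2 - 1 + dc) for dr in range(2) for dc in range(2))
    right = Region((r, size - 1 - c) for r, c in left.pixels)
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(left, right)


# ---------------------------------------------------------------------------
# checkerboards, shadows, transparency strips
# ---------------------------------------------------------------------------


def _checkerboard(size: int, check: int, a: float, b: float) -> np.ndarray:
    """``a`` on even-parity checks, ``b`` on odd."""
    values = np.empty((size, size), dtype=float)
    for r in range(size):
        for c in range(size):
            values[r, c] = a if ((r // check) + (c // check)) % 2 == 0 else b
    return values


def _checkerboard_assimilation(size, dark, bright, target):
    check = 2
    values = _checkerboard(size, check, dark, bright)
    # left target replaces a dark-parity check (edge neighbours bright),
    # right target a bright-parity check (edge neighbours dark).
    li, lj = 3, 3
    ri, rj = 4, 5
    left = Region((li * check + dr, lj * check + dc)
                  for dr in range(check) for dc in range(check))
    right = Region((ri * check + dr, rj * check + dc)
                   for dr in range(check) for dc in range(check))
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(left, right)


def _scs(size, light, dark, shadow_factor, aligned: bool):
    """Checkerboard with a simulated shadow over its right part.

    In-shadow light tiles equal out-of-shadow dark tiles in luminance
    (``light * shadow_factor == dark`` with the defaults).  With
    ``aligned=False`` the shadow boundary crosses tile interiors and creates
    sign-invariant X-junctions where it crosses horizontal tile edges; with
    ``aligned=True`` (the control) it coincides with tile edges and no
    sign-invariant colinear pair exists anywhere in the image.
    """
    tile = size // 4
    values = _checkerboard(size, tile, light, dark)
    shadow_col = 2 * tile if aligned else 2 * tile + 1
    values[:, shadow_col:] *= shadow_factor
    # left target: inner 2×2 of an in-shadow light tile; right target: inner
    # 2×2 of an out-of-shadow dark tile.  Equal luminance by construction.
    lt_r, lt_c = tile, 3 * tile          # tile (1,3): light parity
    rt_r, rt_c = tile, 0                 # tile (1,0): dark parity
    left = Region((lt_r + 1 + dr, lt_c + 1 + dc) for dr in range(2) for dc in range(2))
    right = Region((rt_r + 1 + dr, rt_c + 1 + dc) for dr in range(2) for dc in range(2))
    return LuminanceImage(values), TargetSpec(left, right)


def _strip_figure(size, light, dark, factor, strips, target, left_pos, right_pos,
                  horizontal=False, edit=None):
    """Checkerboard crossed by translucent strips, with two gray targets.

    ``strips`` is a list of (start, stop) spans (columns, or rows when
    ``horizontal``).  Strip boundaries that cross check interiors create
    sign-invariant X-junctions (transparency cue); boundaries aligned with
    check edges do not.  ``edit`` optionally remaps the composed image's
    darkest or brightest pixels (the Argyle/Snake "control" manipulations).
    """
    check = 2
    values = _checkerboard(size, check, light, dark)
    for start, stop in strips:
        if horizontal:
            values[start:stop, :] *= factor
        else:
            values[:, start:stop] *= factor
    if edit is not None:
        which, new = edit
        cur = values.min() if which == "darkest" else values.max()
        values[np.isclose(values, cur)] = new
    left = Region((r + dr, c + dc) for (r, c) in [left_pos]
                  for dr in range(2) for dc in range(2))
    right = Region((r + dr, c + dc) for (r, c) in [right_pos]
                   for dr in range(2) for dc in range(2))
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(left, right)


# ---------------------------------------------------------------------------
# Koffka ring family
# ---------------------------------------------------------------------------


def _koffka(size, field_dark, field_bright, ring, variant: str):
    values = np.empty((size, size), dtype=float)
    h = size // 2
    values[:, :h] = field_dark
    values[:, h:] = field_bright

    def ring_pixels(r0, c0, outer, width):
        px = set()
        for r in range(r0, r0 + outer):
            for c in range(c0, c0 + outer):
                if (r < r0 + width or r >= r0 + outer - width
                        or c < c0 + width or c >= c0 + outer - width):
                    px.add((r, c))
        return px

    outer, width = size // 2, 2
    r0 = c0 = size // 4
    px = ring_pixels(r0, c0, outer, width)
    left_px = {(r, c) for r, c in px if c < h}
    right_px = {(r, c) for r, c in px if c >= h}
    if variant == "broken":
        left_px = {(r, c) for r, c in left_px if c < h - 1}
        right_px = {(r, c) for r, c in right_px if c > h}
    elif variant == "adelson":
        left_px = {(r - 2, c) for r, c in left_px if c < h - 1}
        right_px = {(r + 2, c) for r, c in right_px if c > h}
    for r, c in left_px | right_px:
        values[r, c] = ring
    return LuminanceImage(values), TargetSpec(Region(left_px), Region(right_px))


# ---------------------------------------------------------------------------
# remaining White-effect variants (gallery)
# ---------------------------------------------------------------------------


def _anderson_variant(size, dark, bright, target, target_len):
    half = size // 8
    values = np.empty((size, size), dtype=float)
    for r in range(size):
        values[r, :] = dark if _stripe_of(r, half) % 2 == 0 else bright
    lc0 = (size - target_len) // 2
    # asymmetric straddles: left bar dark-into-bright, right bar fully bright
    left = Region((2 * half - 1 + dr, lc0 + c) for dr in range(2) for c in range(target_len))
    right = Region((5 * half + dr, size - 1 - (lc0 + c))
                   for dr in range(2) for c in range(target_len))
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(left, right)


def _todorovic_variant(size, dark, bright, target):
    tile = size // 4
    values = _checkerboard(size, tile, dark, bright)

    def plus(cr, cc):
        return {(cr, cc), (cr - 1, cc), (cr + 1, cc), (cr, cc - 1), (cr, cc + 1)}

    left_px = plus(size // 4 + 1, size // 4 + 1)
    right_px = plus(3 * size // 4 - 2, 3 * size // 4 - 2)
    for r, c in left_px | right_px:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(Region(left_px), Region(right_px))


def _clifford_zigzag(size, dark, bright, target):
    values = np.empty((size, size), dtype=float)
    for r in range(size):
        for c in range(size):
            values[r, c] = dark if ((r + c) // 2) % 2 == 0 else bright
    left = Region((5, 2 + c) for c in range(4))
    right = Region((10, 10 + c) for c in range(4))
    for r, c in left.pixels | right.pixels:
        values[r, c] = target
    return LuminanceImage(values), TargetSpec(left, right)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def _build_white(recipe: StimulusRecipe, **over):
    pal = {"dark": 17.5, "bright": 70.0, "target": 35.0}
    pal.update(recipe.palette)
    kw = dict(size=recipe.size, frequency=4, target_len=8, target_width=1)
    kw.update(over)
    kw.update(recipe.params)
    return white_stimulus(dark=pal["dark"], bright=pal["bright"],
                          target=pal["target"], **kw)


def _pal(recipe, defaults):
    pal = dict(defaults)
    pal.update(recipe.palette)
    return pal


_BUILDERS: dict[str, Callable[[StimulusRecipe], tuple[LuminanceImage, TargetSpec]]] = {
    "white": lambda rc: _build_white(rc),
    "white_double_increment": lambda rc: _build_white(
        dataclasses.replace(
            rc, palette={"dark": 40.0, "bright": 70.0, "target": 35.0, **rc.palette})),
    "white_double_decrement": lambda rc: _build_white(
        dataclasses.replace(
            rc, palette={"dark": 10.0, "bright": 30.0, "target": 35.0, **rc.palette})),
    "white_narrow_targets": lambda rc: _build_white(rc, target_len=4),
    "white_tall_targets": lambda rc: _build_white(rc, target_width=5),
    "howe_control": lambda rc: _howe_control(
        rc.size, **_pal(rc, {"dark": 17.5, "bright": 70.0, "target": 35.0}),
        target_len=rc.params.get("target_len", 8)),
    "anderson_variant": lambda rc: _anderson_variant(
        rc.size, **_pal(rc, {"dark": 17.5, "bright": 70.0, "target": 35.0}),
        target_len=rc.params.get("target_len", 8)),
    "slc": lambda rc: _slc(
        rc.size, **_pal(rc, {"field_dark": 10.0, "field_bright": 70.0, "target": 35.0}),
        articulated=False),
    "articulated_slc": lambda rc: _slc(
        rc.size, **_pal(rc, {"field_dark": 10.0, "field_bright": 70.0, "target": 35.0}),
        articulated=True),
    "checkerboard_assimilation": lambda rc: _checkerboard_assimilation(
        rc.size, **_pal(rc, {"dark": 17.5, "bright": 70.0, "target": 35.0})),
    "scs": lambda rc: _scs(
        rc.size, **_pal(rc, {"light": 70.0, "dark": 30.0, "shadow_factor": 3.0 / 7.0}),
        aligned=False),
    "scs_control": lambda rc: _scs(
        rc.size, **_pal(rc, {"light": 70.0, "dark": 30.0, "shadow_factor": 3.0 / 7.0}),
        aligned=True),
    "koffka_broken": lambda rc: _koffka(
        rc.size, **_pal(rc, {"field_dark": 10.0, "field_bright": 70.0, "ring": 35.0}),
        variant="broken"),
    "koffka_adelson": lambda rc: _koffka(
        rc.size, **_pal(rc, {"field_dark": 10.0, "field_bright": 70.0, "ring": 35.0}),
        variant="adelson"),
    "koffka_connected": lambda rc: _koffka(
        rc.size, **_pal(rc, {"field_dark": 10.0, "field_bright": 70.0, "ring": 35.0}),
        variant="connected"),
    "todorovic_variant": lambda rc: _todorovic_variant(
        rc.size, **_pal(rc, {"dark": 17.5, "bright": 70.0, "target": 35.0})),
    "clifford_zigzag": lambda rc: _clifford_zigzag(
        rc.size, **_pal(rc, {"dark": 17.5, "bright": 70.0, "target": 35.0})),
}


def _argyle_like(rc, strips, left_pos, right_pos, horizontal, edit=None):
    pal = _pal(rc, {"light": 60.0, "dark": 20.0, "factor": 0.5, "target": 35.0})
    return _strip_figure(rc.size, pal["light"], pal["dark"], pal["factor"],
                         strips, pal["target"], left_pos, right_pos,
                         horizontal=horizontal, edit=edit)


_BUILDERS.update({
    # translucent strips crossing check interiors -> sign-invariant junctions
    "argyle": lambda rc: _argyle_like(
        rc, [(3, 7), (11, 15)], (7, 4), (7, 8), horizontal=False),
    "long_range_argyle": lambda rc: _argyle_like(
        rc, [(3, 7)], (7, 4), (7, 12), horizontal=False),
    # strips aligned with check edges -> the transparency cue is destroyed
    "broken_argyle": lambda rc: _argyle_like(
        rc, [(4, 8), (12, 16)], (7, 5), (7, 9), horizontal=False),
    "argyle_control_1": lambda rc: _argyle_like(
        rc, [(3, 7), (11, 15)], (7, 4), (7, 8), horizontal=False,
        edit=("darkest", rc.params.get("edit_to", 25.0))),
    "argyle_control_2": lambda rc: _argyle_like(
        rc, [(3, 7), (11, 15)], (7, 4), (7, 8), horizontal=False,
        edit=("brightest", rc.params.get("edit_to", 28.0))),
    "snake": lambda rc: _argyle_like(
        rc, [(3, 7)], (4, 3), (9, 11), horizontal=True),
    "snake_control": lambda rc: _argyle_like(
        rc, [(4, 8)], (5, 3), (9, 11), horizontal=True),
    "snake_control_1": lambda rc: _argyle_like(
        rc, [(3, 7)], (4, 3), (9, 11), horizontal=True,
        edit=("darkest", rc.params.get("edit_to", 25.0))),
    "snake_control_2": lambda rc: _argyle_like(
        rc, [(3, 7)], (4, 3), (9, 11), horizontal=True,
        edit=("brightest", rc.params.get("edit_to", 28.0))),
})

RECIPE_NAMES = tuple(sorted(_BUILDERS))

#: the twelve classic figures of the main comparison table
TABLE1_FIGURES = (
    "argyle", "long_range_argyle", "broken_argyle", "snake", "snake_control",
    "koffka_broken", "koffka_adelson", "koffka_connected", "slc",
    "articulated_slc", "white", "checkerboard_assimilation",
)


def make_stimulus(recipe: StimulusRecipe | str) -> tuple[LuminanceImage, TargetSpec]:
    """Build the named figure at its default geometry and palette.

    ``recipe`` may be a bare name or a :class:`StimulusRecipe` carrying
    geometry/palette overrides.  Deterministic: the same recipe always yields
    the same image and targets.
    """
    if isinstance(recipe, str):
        recipe = StimulusRecipe(recipe)
    try:
        builder = _BUILDERS[recipe.name]
    except KeyError:
        raise ValueError(
            f"unknown stimulus {recipe.name!r}; known: {', '.join(RECIPE_NAMES)}"
        ) from None
    img, spec = builder(recipe)
    spec.validate(img)
    return img, spec


def noised_slc_batch(
    noise_levels=(1.0, 2.0, 3.0, 4.0, 5.0),
    n_per_level: int = 10,
    seed: int = 0,
) -> list[NoisedStimulus]:
    """Noise-robustness inputs: upsampled SLC images with pixel-wise noise.

    The 16×16 SLC figure is pixel-replicated to 32×32 (so a single pixel's
    noise has moderate influence), each pixel receives an independent draw
    from Uniform(−k, +k) for noise level ``k``, and the left target region is
    then copied onto the right one so the two targets are physically
    identical.  ``n_per_level`` images per level, reproducible from ``seed``.
    """
    base_img, base_spec = make_stimulus("slc")
    img2 = upsample(base_img, 2)
    spec2 = base_spec.upsampled(2)
    rng = np.random.default_rng(seed)
    out: list[NoisedStimulus] = []
    for level in noise_levels:
        for i in range(n_per_level):
            noised = add_uniform_noise(img2, float(level), rng)
            noised = copy_region(noised, spec2.left, spec2.right)
            out.append(NoisedStimulus(float(level), i, noised, spec2))
    return out
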