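"""Calibrated luminance images and the transformations used by the experiments.

A :class:`LuminanceImage` is a rectangular grid of photometric luminances in
cd/m², row 0 at the top, 0-based ``(row, col)`` coordinates.  Values are raw
linear luminances: no gamma or display encoding is ever applied to model
inputs (PNG export is a visualization convenience only).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "LuminanceImage",
    "Region",
    "read_luminance_csv",
    "upsample",
    "add_uniform_noise",
    "copy_region",
    "write_maps",
]


@dataclasses.dataclass(frozen=True)
class LuminanceImage:
    """An m×n grid of luminances in cd/m².

    Invariants: rectangular, all values finite and non-negative.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"luminance image must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("luminance values must be finite")
        if np.any(arr < 0):
            raise ValueError("luminance cannot be negative")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, LuminanceImage):
            return NotImplemented
        return self.shape == other.shape and bool(np.all(self.values == other.values))


@dataclasses.dataclass(frozen=True)
class Region:
    """A non-empty set of 0-based ``(row, col)`` pixel coordinates."""

    pixels: frozenset[tuple[int, int]]

    def __init__(self, pixels: Iterable[tuple[int, int]]):
        px = frozenset((int(r), int(c)) for r, c in pixels)
        if not px:
            raise ValueError("region must be non-empty")
        object.__setattr__(self, "pixels", px)

    def __len__(self) -> int:
        return len(self.pixels)

    def __iter__(self):
        return iter(sorted(self.pixels))

    def validate(self, img: LuminanceImage) -> None:
        for r, c in self.pixels:
            if not (0 <= r < img.m and 0 <= c < img.n):
                raise ValueError(f"pixel {(r, c)} outside {img.shape} image")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), inclusive."""
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return min(rows), min(cols), max(rows), max(cols)

    def offsets(self) -> frozenset[tuple[int, int]]:
        """Pixel offsets relative to the bounding-box origin (shape signature)."""
        r0, c0, _, _ = self.bounding_box()
        return frozenset((r - r0, c - c0) for r, c in self.pixels)

    def upsampled(self, factor: int) -> "Region":
        """The region covering the same area after pixel-replication upsampling."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return Region(
            (r * factor + dr, c * factor + dc)
            for r, c in self.pixels
            for dr in range(factor)
            for dc in range(factor)
        )

    def values_in(self, arr: np.ndarray) -> np.ndarray:
        """Values of ``arr`` over the region, in sorted-coordinate order."""
        coords = sorted(self.pixels)
        return np.array([arr[r, c] for r, c in coords])


def read_luminance_csv(path: str | Path) -> LuminanceImage:
    """Read a comma-separated matrix of luminances (cd/m²), row 0 = top row.

    Raises a format error for ragged rows and a value error for negative or
    non-numeric cells.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell on line {ln}") from exc
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty luminance file")
    width = len(rows[0])
    for ln, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row on line {ln} (expected {width} cells)")
    return LuminanceImage(np.array(rows, dtype=float))


def write_luminance_csv(img: LuminanceImage | np.ndarray, path: str | Path) -> None:
    arr = img.values if isinstance(img, LuminanceImage) else np.asarray(img)
    np.savetxt(path, arr, delimiter=",", fmt="%.10g")


def upsample(img: LuminanceImage, factor: int) -> LuminanceImage:
    """Replicate every pixel into a ``factor``×``factor`` block.

    Nearest-neighbour replication is used deliberately: interpolation would
    introduce luminances absent from the stimulus palette.
    """
    if factor < 1:
        raise ValueError("upsample factor must be >= 1")
    return LuminanceImage(np.repeat(np.repeat(img.values, factor, axis=0), factor, axis=1))


def add_uniform_noise(
    img: LuminanceImage, limit: float, rng: np.random.Generator
) -> LuminanceImage:
    """Add independent Uniform(−limit, +limit) noise to each pixel.

    Results are clipped below at 0 cd/m²: physical luminance cannot be
    negative.  Deterministic for a given generator state.
    """
    if limit < 0:
        raise ValueError("noise limit must be >= 0")
    noise = rng.uniform(-limit, limit, size=img.shape)
    return LuminanceImage(np.clip(img.values + noise, 0.0, None))


def copy_region(img: LuminanceImage, src: Region, dst: Region) -> LuminanceImage:
    """Copy the pixels of ``src`` onto ``dst`` (aligned by bounding boxes).

    The two regions must be congruent (identical offset patterns).  Used to
    make the two targets of a noised stimulus physically identical.
    """
    src.validate(img)
    dst.validate(img)
    if src.offsets() != dst.offsets():
        raise ValueError("source and destination regions are not congruent")
    out = img.values.copy()
    sr0, sc0, _, _ = src.bounding_box()
    dr0, dc0, _, _ = dst.bounding_box()
    for r, c in src.pixels:
        out[r - sr0 + dr0, c - sc0 + dc0] = img.values[r, c]
    return LuminanceImage(out)


def write_maps(dec, prefix: str | Path, png: bool = False) -> list[Path]:
    """Write a decomposition to disk.

    Produces ``<prefix>.illuminance.csv`` (lux), ``<prefix>.reflectance.csv``
    (proportion), ``<prefix>.glow.csv`` (0/1) and ``<prefix>.report.json``
    (energy, seed, schedule, iterations, runs).  With ``png=True`` also writes
    linearly scaled grayscale renderings.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr, fmt in [
        ("illuminance", dec.illuminance, "%.10g"),
        ("reflectance", dec.reflectance, "%.10g"),
        ("glow", dec.glow_mask.astype(int), "%d"),
    ]:
        p = prefix.with_suffix(f".{name}.csv")
        np.savetxt(p, arr, delimiter=",", fmt=fmt)
        written.append(p)
    report = {
        "energy": float(dec.energy),
        "seed": int(dec.seed),
        "schedule": dec.schedule,
        "iterations": int(dec.iterations),
        "runs_used": int(dec.runs_used),
    }
    rp = prefix.with_suffix(".report.json")
    rp.write_text(json.dumps(report, indent=2))
    written.append(rp)
    if png:
        from PIL import Image as PILImage

        for name, arr in [("illuminance", dec.illuminance), ("reflectance", dec.reflectance)]:
            lo, hi = float(arr.min()), float(arr.max())
            scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
            im = PILImage.fromarray((scaled * 255).astype(np.uint8), mode="L")
            p = prefix.with_suffix(f".{name}.png")
            im.save(p)
            written.append(p)
    return written
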