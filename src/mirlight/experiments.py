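"""The illusion-experiment battery: main-figure table, noise robustness,
stripe-luminance grid, frequency sweep, and the variant gallery.

The central statistic is the illusion magnitude: the difference between the
mean predicted reflectance over the "left" and "right" target regions
(left − right).  A positive magnitude means the left target is predicted
lighter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .crf import Decomposition, ModelConfig, best_of_runs
from .image import LuminanceImage
from .stimuli import (
    TABLE1_FIGURES,
    TargetSpec,
    make_stimulus,
    noised_slc_batch,
    white_stimulus,
)

logger = logging.getLogger("mirlight")

__all__ = [
    "IllusionResult",
    "GridResult",
    "illusion_magnitude",
    "decompose",
    "table1_experiment",
    "noise_experiment",
    "stripe_grid_experiment",
    "frequency_experiment",
    "gallery_experiment",
]


@dataclasses.dataclass
class IllusionResult:
    stimulus: str
    left_mean: float
    right_mean: float
    magnitude: float  # always left_mean - right_mean
    model: str = ""
    energy: float = float("nan")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GridResult:
    """Illusion magnitude per (darker-stripe, brighter-stripe) luminance.

    ``cells[i, j]`` is the magnitude for ``rows[i]`` (darker) × ``cols[j]``
    (brighter); NaN marks the excluded conditions where the darker stripe's
    luminance equals or exceeds the brighter one's.
    """

    rows: np.ndarray
    cols: np.ndarray
    cells: np.ndarray
    target: float
    model: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.rows, columns=self.cols)


def illusion_magnitude(
    dec: Decomposition, targets: TargetSpec, stimulus: str = "", model: str = ""
) -> IllusionResult:
    """Mean reflectance over the left target region minus the right one."""
    if not targets.left.pixels or not targets.right.pixels:
        raise ValueError("target regions must be non-empty")
    left = float(np.mean(targets.left.values_in(dec.reflectance)))
    right = float(np.mean(targets.right.values_in(dec.reflectance)))
    return IllusionResult(
        stimulus=stimulus,
        left_mean=left,
        right_mean=right,
        magnitude=left - right,
        model=model,
        energy=dec.energy,
    )


def decompose(
    img: LuminanceImage,
    model: str = "modified",
    runs: int = 30,
    seed: int = 0,
    cfg: ModelConfig | None = None,
) -> Decomposition:
    """Best-of-``runs`` decomposition under one of the two model regimes."""
    if cfg is None:
        cfg = ModelConfig.preset(model)
    cfg = dataclasses.replace(cfg, runs=runs, seed=seed)
    dec = best_of_runs(img, cfg)
    logger.debug(
        "decompose model=%s seed=%d config=%s energy=%.4f",
        model, seed, _config_hash(cfg), dec.energy,
    )
    return dec


def _config_hash(cfg: ModelConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _emit(out_dir, name, table: pd.DataFrame, manifest: dict) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=2))


def table1_experiment(
    variants=("modified", "original"),
    runs: int = 30,
    seed: int = 0,
    figures=TABLE1_FIGURES,
    out_dir=None,
) -> pd.DataFrame:
    """Left/right predicted reflectance for the twelve classic figures.

    Per figure and model variant: mean target reflectances, magnitude, and
    the energy of the kept run.  Unknown figures are skipped with a warning.
    """
    records = []
    for name in figures:
        try:
            img, targets = make_stimulus(name)
        except ValueError:
            logger.warning("skipping unknown stimulus %r", name)
            continue
        for model in variants:
            dec = decompose(img, model=model, runs=runs, seed=seed)
            res = illusion_magnitude(dec, targets, stimulus=name, model=model)
            logger.info(
                "table1 %s/%s: left=%.3f right=%.3f energy=%.2f",
                name, model, res.left_mean, res.right_mean, res.energy,
            )
            records.append(res.as_dict())
    frame = pd.DataFrame.from_records(records)
    _emit(out_dir, "table1", frame, {"seed": seed, "runs": runs, "figures": list(figures)})
    return frame


def noise_experiment(
    seed: int = 0,
    models=("modified", "original"),
    noise_levels=(1.0, 2.0, 3.0, 4.0, 5.0),
    n_per_level: int = 10,
    runs: int = 10,
    out_dir=None,
) -> pd.DataFrame:
    """Noise robustness on the upsampled SLC figure.

    For each noise level, ``n_per_level`` independently noised images (with
    physically identical targets) are each decomposed with best-of-``runs``;
    the per-level mean and standard deviation of the magnitude are reported.
    """
    batch = noised_slc_batch(noise_levels, n_per_level, seed)
    records = []
    for model in models:
        for stim in batch:
            dec = decompose(
                stim.image, model=model, runs=runs, seed=seed + 1000 * stim.index
            )
            res = illusion_magnitude(
                dec, stim.targets, stimulus=f"noised_slc_{stim.level:g}", model=model
            )
            records.append({**res.as_dict(), "level": stim.level, "index": stim.index})
    raw = pd.DataFrame.from_records(records)
    summary = (
        raw.groupby(["model", "level"])["magnitude"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "magnitude_mean", "std": "magnitude_sd"})
    )
    _emit(out_dir, "noise_raw", raw, {"seed": seed, "runs": runs})
    _emit(out_dir, "noise_summary", summary, {"seed": seed, "runs": runs})
    return summary


def stripe_grid_experiment(
    model: str = "modified",
    dark_levels=None,
    bright_levels=None,
    target: float = 35.0,
    runs: int = 5,
    seed: int = 0,
    out_dir=None,
) -> GridResult:
    """Magnitude heatmap over (darker, brighter) stripe luminances.

    Defaults sweep 10–68 (darker) × 12–70 cd/m² (brighter) in 2-cd/m² steps
    with the target fixed at 35 cd/m²; conditions with ``dark >= bright`` are
    excluded.  The target lies between the stripes inside the "frame" of the
    grid and in double increments/decrements outside it.
    """
    dark_levels = np.asarray(
        dark_levels if dark_levels is not None else np.arange(10.0, 69.0, 2.0)
    )
    bright_levels = np.asarray(
        bright_levels if bright_levels is not None else np.arange(12.0, 71.0, 2.0)
    )
    cells = np.full((dark_levels.size, bright_levels.size), np.nan)
    for i, dark in enumerate(dark_levels):
        for j, bright in enumerate(bright_levels):
            if dark >= bright:
                continue
            img, targets = white_stimulus(dark=float(dark), bright=float(bright),
                                          target=target)
            dec = decompose(img, model=model, runs=runs, seed=seed)
            cells[i, j] = illusion_magnitude(dec, targets).magnitude
    result = GridResult(dark_levels, bright_levels, cells, target, model)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.frame().to_csv(out / f"stripe_grid_{model}.csv")
        _plot_grid(result, out / f"stripe_grid_{model}.png")
        (out / f"stripe_grid_{model}.manifest.json").write_text(
            json.dumps({"seed": seed, "runs": runs, "target": target}, indent=2)
        )
    return result


def _plot_grid(result: GridResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        result.cells, origin="lower", aspect="auto", cmap="inferno",
        extent=(result.cols[0], result.cols[-1], result.rows[0], result.rows[-1]),
    )
    ax.set_xlabel("brighter stripe luminance (cd/m²)")
    ax.set_ylabel("darker stripe luminance (cd/m²)")
    ax.set_title(f"illusion magnitude, {result.model} model")
    fig.colorbar(im, ax=ax, label="left − right reflectance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def frequency_experiment(
    frequencies=(2, 4, 8),
    model: str = "modified",
    runs: int = 30,
    seed: int = 0,
    out_dir=None,
) -> list[IllusionResult]:
    """Stripe-frequency sweep of the White figure at the standard palette."""
    results = []
    for f in frequencies:
        img, targets = white_stimulus(frequency=int(f))
        dec = decompose(img, model=model, runs=runs, seed=seed)
        results.append(
            illusion_magnitude(dec, targets, stimulus=f"white_f{f}", model=model)
        )
    frame = pd.DataFrame.from_records([r.as_dict() for r in results])
    _emit(out_dir, f"frequency_{model}", frame, {"seed": seed, "runs": runs})
    return results


def gallery_experiment(
    names=None, model: str = "modified", runs: int = 30, seed: int = 0, out_dir=None
) -> pd.DataFrame:
    """Run every named figure (or a subset) under one model variant."""
    from .stimuli import RECIPE_NAMES

    names = list(names) if names is not None else list(RECIPE_NAMES)
    records = []
    for name in names:
        img, targets = make_stimulus(name)
        dec = decompose(img, model=model, runs=runs, seed=seed)
        res = illusion_magnitude(dec, targets, stimulus=name, model=model)
        records.append(res.as_dict())
    frame = pd.DataFrame.from_records(records)
    _emit(out_dir, f"gallery_{model}", frame, {"seed": seed, "runs": runs})
    return frame
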