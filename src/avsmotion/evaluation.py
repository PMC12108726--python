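"""Benchmark experiments: cluster balance, subsample retraining, accuracy grid.

The accuracy grid measures the fraction of trials whose detected global
motion direction matches the generated one, over a grid of object sizes and
static-noise fractions. Trials are balanced across the eight directions;
the default of 800 trials per cell (100 per direction) makes each cell an
integer multiple of 0.125%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .avs import LabelDirectionMap, MotionDirectionAVS, calibrate_labels
from .directions import N_DIRECTIONS
from .mixture import FitResult
from .stimuli import (
    TrainingSet,
    apply_noise_type1,
    enumerate_ideal_dataset,
    generate_frame_pair,
    generate_object_mask,
)

__all__ = [
    "AccuracyTable",
    "ClusterReport",
    "run_accuracy_grid",
    "run_trial",
    "cluster_report",
    "subsample_experiment",
]


@dataclass
class AccuracyTable:
    """Size x noise grid of detection accuracies."""

    table: pd.DataFrame  # index: sizes, columns: noise fractions
    trials_per_cell: int
    seed: int

    def cell(self, size: int, noise: float) -> float:
        return float(self.table.loc[size, noise])


@dataclass
class ClusterReport:
    """Diagnostics of one training run."""

    per_label_counts: np.ndarray
    purity: float
    label_map_ok: bool
    n_iter: int


def run_trial(
    model: MotionDirectionAVS,
    size: int,
    noise: float,
    direction: int,
    rng: np.random.Generator,
    color_mode: str = "rgb",
) -> bool:
    """One stimulus/detect trial; True when the detected direction is correct."""
    h, w = model.grid_shape
    mask = generate_object_mask(size, h, w, direction, rng)
    pair = generate_frame_pair(mask, direction, color_mode, rng, h, w)
    if noise > 0:
        # scene noise never sits on the object (at either time)
        pair = apply_noise_type1(
            pair, noise, rng, exclude_cells=mask.cells | mask.translated(direction)
        )
    return model.detect(pair).global_direction == direction


def run_accuracy_grid(
    sizes: list[int],
    noise_levels: list[float],
    trials_per_cell: int,
    model: MotionDirectionAVS,
    seed: int,
    color_mode: str = "rgb",
) -> AccuracyTable:
    """Accuracy over every (object size, noise fraction) cell.

    Each cell runs ``trials_per_cell`` independent trials cycling through the
    eight directions, so the directions are balanced whenever
    ``trials_per_cell`` is a multiple of 8.
    """
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.empty((len(sizes), len(noise_levels)))
    for i, size in enumerate(sizes):
        for j, noise in enumerate(noise_levels):
            correct = sum(
                run_trial(model, size, noise, t % N_DIRECTIONS, rng, color_mode)
                for t in range(trials_per_cell)
            )
            grid[i, j] = correct / trials_per_cell
    table = pd.DataFrame(grid, index=sizes, columns=noise_levels)
    table.index.name = "size"
    table.columns.name = "noise"
    return AccuracyTable(table, trials_per_cell, seed)


def cluster_report(
    model: MotionDirectionAVS | FitResult,
    truth: TrainingSet,
) -> ClusterReport:
    """Per-label counts, purity and label-map status for a fitted model."""
    from .mixture import assign

    if isinstance(model, FitResult):
        labels = assign(model.params, truth.vectors)
        n_iter = model.n_iter
        try:
            calibrate_labels(model.params)
            map_ok = True
        except Exception:
            map_ok = False
    else:
        labels = model.gmm_.predict(truth.vectors)
        n_iter = model.gmm_.n_iter_
        map_ok = True  # fit() would have raised otherwise
    counts = np.bincount(labels, minlength=N_DIRECTIONS)
    correct = 0
    for k in range(N_DIRECTIONS):
        member = truth.truth_direction[labels == k]
        if member.size:
            correct += int(np.bincount(member).max())
    return ClusterReport(counts, correct / len(truth), map_ok, n_iter)


def subsample_experiment(
    fraction: float,
    seed: int,
    grid_shape: tuple[int, int] = (32, 32),
    **config,
) -> tuple[ClusterReport, LabelDirectionMap]:
    """Retrain on a uniform random subsample of the ideal dataset.

    Returns the cluster diagnostics on the subsample and the (possibly
    permuted relative to a full-data run) label-to-direction map.
    """
    full = enumerate_ideal_dataset(*grid_shape)
    rng = np.random.default_rng(seed)
    if round(fraction * len(full)) < N_DIRECTIONS:
        raise ValueError("subsample too small to support 8 components")
    sub = full.subsample(fraction, rng)
    model = MotionDirectionAVS(
        grid_shape=grid_shape, random_state=int(rng.integers(2**31)), **config
    ).fit(sub)
    report = cluster_report(model, sub)
    return report, model.label_map_
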