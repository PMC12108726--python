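"""Synthetic motion stimuli.

Generates the inputs the system is trained and tested on:

* frame pairs showing a uniformly colored object translated by exactly one
  pixel on a uniformly colored background (object and background colors drawn
  at random per trial and constant across the two frames);
* static pixel noise — randomly colored pixels written at random positions
  identically into both frames, so the noise itself carries no motion;
* the ideal index-vector training set: the identity output of every
  direction-selective neuron of the retinal grid, one vector per
  (row, col, direction) triple.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .directions import DIRECTION_OFFSETS, N_DIRECTIONS

__all__ = [
    "FramePair",
    "ObjectMask",
    "TrainingSet",
    "generate_object_mask",
    "generate_frame_pair",
    "apply_noise_type1",
    "enumerate_ideal_dataset",
]


@dataclass
class FramePair:
    """Two same-shape images at times t and t + one frame step."""

    frame_t: np.ndarray
    frame_t1: np.ndarray

    def __post_init__(self) -> None:
        self.frame_t = np.asarray(self.frame_t)
        self.frame_t1 = np.asarray(self.frame_t1)
        if self.frame_t.shape != self.frame_t1.shape:
            raise ValueError(
                f"frames differ in shape: {self.frame_t.shape} vs {self.frame_t1.shape}"
            )
        if self.frame_t.ndim not in (2, 3):
            raise ValueError(f"frames must be HxW or HxWx3, got shape {self.frame_t.shape}")
        if self.frame_t.ndim == 3 and self.frame_t.shape[2] != 3:
            raise ValueError(f"color frames must have 3 channels, got {self.frame_t.shape[2]}")
        for f in (self.frame_t, self.frame_t1):
            if f.size and (f.min() < 0 or f.max() > 255):
                raise ValueError("pixel values must lie in [0, 255]")

    @property
    def color_mode(self) -> str:
        return "rgb" if self.frame_t.ndim == 3 else "grayscale"

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame_t.shape[:2]


@dataclass
class ObjectMask:
    """A set of grid cells occupied by the moving object at time t."""

    cells: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        self.cells = frozenset((int(r), int(c)) for r, c in self.cells)

    @property
    def n_pixels(self) -> int:
        return len(self.cells)

    def translated(self, direction: int) -> frozenset[tuple[int, int]]:
        dr, dc = DIRECTION_OFFSETS[direction]
        return frozenset((r + dr, c + dc) for r, c in self.cells)

    def is_connected(self) -> bool:
        """True when the cells form a single 4-connected component."""
        if self.n_pixels <= 1:
            return True
        cells = self.cells
        start = next(iter(cells))
        seen = {start}
        queue = deque([start])
        while queue:
            r, c = queue.popleft()
            for nr, nc in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if (nr, nc) in cells and (nr, nc) not in seen:
                    seen.add((nr, nc))
                    queue.append((nr, nc))
        return len(seen) == len(cells)


@dataclass
class TrainingSet:
    """Normalized index vectors plus their ground-truth tags."""

    vectors: np.ndarray  # N x 16
    truth_direction: np.ndarray  # N, ints 0..7
    truth_position: np.ndarray  # N x 2, (row, col)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.truth_direction = np.asarray(self.truth_direction, dtype=int)
        self.truth_position = np.asarray(self.truth_position, dtype=int)
        n = len(self.vectors)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 2 * N_DIRECTIONS:
            raise ValueError("vectors must be N x 16")
        if len(self.truth_direction) != n or len(self.truth_position) != n:
            raise ValueError("truth tags must align with vectors")

    def __len__(self) -> int:
        return len(self.vectors)

    def subsample(self, fraction: float, rng: np.random.Generator) -> "TrainingSet":
        """Uniform subsample without replacement of a fraction of the vectors."""
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        n = int(round(fraction * len(self)))
        idx = rng.choice(len(self), size=n, replace=False)
        return TrainingSet(
            self.vectors[idx], self.truth_direction[idx], self.truth_position[idx]
        )


def _allowed_rectangle(grid_h: int, grid_w: int, direction: int) -> tuple[int, int, int, int]:
    """Row/col bounds (inclusive) such that a cell and its translate both fit."""
    dr, dc = DIRECTION_OFFSETS[direction]
    r0 = max(0, -dr)
    r1 = grid_h - 1 - max(0, dr)
    c0 = max(0, -dc)
    c1 = grid_w - 1 - max(0, dc)
    return r0, r1, c0, c1


def generate_object_mask(
    n_pixels: int,
    grid_h: int,
    grid_w: int,
    direction: int,
    rng: np.random.Generator,
) -> ObjectMask:
    """Grow a random 4-connected blob of exactly ``n_pixels`` cells.

    The blob is grown by breadth-style random accretion from a random seed
    cell, restricted to the sub-rectangle where both the blob and its 1-pixel
    translate along ``direction`` stay inside the grid.
    """
    if n_pixels < 1:
        raise ValueError(f"n_pixels must be positive, got {n_pixels}")
    r0, r1, c0, c1 = _allowed_rectangle(grid_h, grid_w, direction)
    capacity = (r1 - r0 + 1) * (c1 - c0 + 1)
    if capacity < n_pixels:
        raise ValueError(
            f"object of {n_pixels} pixels cannot fit a {grid_h}x{grid_w} grid "
            f"moving in direction {direction} (capacity {capacity})"
        )
    seed = (int(rng.integers(r0, r1 + 1)), int(rng.integers(c0, c1 + 1)))
    blob = {seed}
    frontier = set()

    def neighbors(cell: tuple[int, int]):
        r, c = cell
        for nr, nc in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if r0 <= nr <= r1 and c0 <= nc <= c1:
                yield nr, nc

    frontier.update(n for n in neighbors(seed))
    while len(blob) < n_pixels:
        pick = tuple(sorted(frontier))[rng.integers(len(frontier))]
        blob.add(pick)
        frontier.discard(pick)
        frontier.update(n for n in neighbors(pick) if n not in blob)
    return ObjectMask(frozenset(blob))


def _random_color(color_mode: str, rng: np.random.Generator) -> np.ndarray:
    if color_mode == "rgb":
        return rng.integers(0, 256, size=3)
    return rng.integers(0, 256, size=())


def generate_frame_pair(
    mask: ObjectMask,
    direction: int,
    color_mode: str,
    rng: np.random.Generator,
    grid_h: int = 32,
    grid_w: int = 32,
) -> FramePair:
    """Render the before/after frames of a 1-pixel object translation.

    Object and background receive independent uniform random colors, redrawn
    until they differ in at least one channel (an object identical to its
    background is undetectable by construction).
    """
    if color_mode not in ("rgb", "grayscale"):
        raise ValueError(f"unknown color_mode {color_mode!r}")
    moved = mask.translated(direction)
    for r, c in mask.cells | moved:
        if not (0 <= r < grid_h and 0 <= c < grid_w):
            raise ValueError("mask (or its translate) does not fit the grid")

    background = _random_color(color_mode, rng)
    obj = _random_color(color_mode, rng)
    while np.array_equal(obj, background):
        obj = _random_color(color_mode, rng)

    shape = (grid_h, grid_w, 3) if color_mode == "rgb" else (grid_h, grid_w)
    frame_t = np.empty(shape, dtype=np.uint8)
    frame_t[...] = background
    frame_t1 = frame_t.copy()
    rows, cols = zip(*mask.cells)
    frame_t[rows, cols] = obj
    rows1, cols1 = zip(*moved)
    frame_t1[rows1, cols1] = obj
    return FramePair(frame_t, frame_t1)


def apply_noise_type1(
    pair: FramePair,
    fraction: float,
    rng: np.random.Generator,
    exclude_cells: frozenset[tuple[int, int]] | set[tuple[int, int]] | None = None,
) -> FramePair:
    """Inject static pixel noise identically into both frames.

    ``round(fraction * H * W)`` distinct positions are chosen uniformly at
    random; each receives one independently drawn random color, written into
    both frames. Because the noise is identical at times t and t+1 it never
    creates a temporal change.

    ``exclude_cells`` lists positions the noise may not touch. The motion
    benchmark passes the object's cells at both times, emulating scene noise
    that does not sit on the moving object — the reading of static noise that
    reproduces the published accuracy pattern. With the default ``None`` the
    positions are drawn over the whole grid, overwriting object or background
    alike.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    h, w = pair.shape
    n = int(round(fraction * h * w))
    if n == 0:
        return FramePair(pair.frame_t.copy(), pair.frame_t1.copy())
    if exclude_cells:
        free = np.array(
            sorted(
                set(range(h * w))
                - {r * w + c for r, c in exclude_cells if 0 <= r < h and 0 <= c < w}
            )
        )
        if len(free) < n:
            raise ValueError(
                f"cannot place {n} noise pixels on {len(free)} free cells"
            )
        flat = rng.choice(free, size=n, replace=False)
    else:
        flat = rng.choice(h * w, size=n, replace=False)
    rows, cols = np.unravel_index(flat, (h, w))
    frame_t = pair.frame_t.copy()
    frame_t1 = pair.frame_t1.copy()
    if pair.color_mode == "rgb":
        colors = rng.integers(0, 256, size=(n, 3), dtype=frame_t.dtype)
    else:
        colors = rng.integers(0, 256, size=n, dtype=frame_t.dtype)
    frame_t[rows, cols] = colors
    frame_t1[rows, cols] = colors
    return FramePair(frame_t, frame_t1)


def enumerate_ideal_dataset(
    grid_h: int = 32,
    grid_w: int = 32,
    a: int = 16,
    norm_const: float | None = None,
) -> TrainingSet:
    """Enumerate the normalized index vector of every neuron of the grid.

    One vector per (row, col, direction) triple — 8 per pixel — giving
    ``grid_h * grid_w * 8`` vectors; for a 32x32 grid that is 8192. Each
    vector is nonzero only at dimensions (2d, 2d+1), holding the offset
    position indices (a + row, a + col) divided by ``norm_const``.
    """
    if grid_h < 1 or grid_w < 1:
        raise ValueError("grid dimensions must be >= 1")
    if norm_const is None:
        norm_const = a + max(grid_h, grid_w) - 1
    if norm_const <= 0:
        raise ValueError(f"norm_const must be positive, got {norm_const}")
    rows, cols, dirs = np.meshgrid(
        np.arange(grid_h), np.arange(grid_w), np.arange(N_DIRECTIONS), indexing="ij"
    )
    rows, cols, dirs = rows.ravel(), cols.ravel(), dirs.ravel()
    n = rows.size
    vectors = np.zeros((n, 2 * N_DIRECTIONS))
    idx = np.arange(n)
    vectors[idx, 2 * dirs] = (a + rows) / norm_const
    vectors[idx, 2 * dirs + 1] = (a + cols) / norm_const
    return TrainingSet(vectors, dirs, np.column_stack([rows, cols]))
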