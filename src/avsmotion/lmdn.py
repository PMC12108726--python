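"""Local Motion Detection Neurons (LMDNs).

Each pixel of the retinal grid hosts eight direction-selective neurons, one
per 45-degree direction. A neuron mimics four retinal cell stages:

* photoreceptors supply the raw pixel values of the two frames;
* the bipolar cell (BC) fires when the pixel's value changes between frames
  — a temporal edge;
* the horizontal cell (HC) fires when the pixel's value at time t differs
  from the value of its neighbor along the preferred direction at time t+1 —
  i.e. it stays silent exactly when the pixel's content reappears one step
  along that direction;
* the ganglion cell (GC) combines the two with AND-NOT logic: the neuron is
  activated when the BC fires (something changed here) and the HC does not
  (the content moved where this neuron expects it).

An activated neuron emits its identity as an 8x2 index matrix whose single
nonzero row (the preferred direction) holds the offset position indices
(a + row, a + col); the matrix is flattened and normalized to a 16-vector for
the unsupervised global layer.

A graded "soft" ganglion mode passes the BC/HC bits through sigmoid synapses
(excitatory for BC, the complement for HC) before thresholding; with the
default synapse parameters it reproduces the hard AND-NOT truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .directions import DIRECTION_OFFSETS, N_DIRECTIONS, DirectionOffset
from .stimuli import FramePair

__all__ = [
    "LMDNConfig",
    "ActivationMap",
    "IndexMatrix",
    "bc_response",
    "hc_response",
    "synapse",
    "gc_output",
    "lmdn_layer",
    "encode_index",
    "normalize_flatten",
    "activated_vectors",
]

#: Luminance weights (ITU-R BT.601) used by the luminance color rule.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LMDNConfig:
    """Parameters of the local motion detection layer.

    threshold_L
        Minimum absolute pixel-value difference counted as a change. The
        default 0 activates on any nonzero difference, appropriate for
        uniformly colored synthetic stimuli; raise it for graded images.
    a
        Offset added to the position indices so no index is zero.
    norm_const
        Divisor mapping indices into [0, 1]; ``None`` resolves to
        ``a + max(H, W) - 1`` for the grid at hand (47 for 32x32, a=16).
    synapse_k, synapse_omega, synapse_theta
        Sigmoid synapse steepness, weight and threshold (soft ganglion mode).
    gc_threshold
        Activation cutoff applied to the soft ganglion product.
    color_rule
        ``any_channel``: a pixel differs when any RGB channel differs by more
        than L. ``luminance``: compare BT.601 luminance instead.
    """

    threshold_L: float = 0.0
    a: int = 16
    norm_const: float | None = None
    synapse_k: float = 10.0
    synapse_omega: float = 1.0
    synapse_theta: float = 0.5
    gc_threshold: float = 0.5
    color_rule: str = "any_channel"

    def __post_init__(self) -> None:
        if self.threshold_L < 0:
            raise ValueError("threshold_L must be >= 0")
        if self.a < 1:
            raise ValueError("index offset a must be >= 1")
        if not 0 < self.gc_threshold < 1:
            raise ValueError("gc_threshold must lie in (0, 1)")
        if not 0 < self.synapse_theta <= self.synapse_omega:
            raise ValueError("excitatory synapse requires 0 < theta <= omega")
        if self.color_rule not in ("any_channel", "luminance"):
            raise ValueError(f"unknown color_rule {self.color_rule!r}")

    def resolve_norm_const(self, grid_h: int, grid_w: int) -> float:
        if self.norm_const is not None:
            return self.norm_const
        return self.a + max(grid_h, grid_w) - 1


@dataclass
class ActivationMap:
    """Per-pixel, per-direction binary activation of the LMDN layer."""

    bits: np.ndarray  # H x W x 8, bool

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3 or self.bits.shape[2] != N_DIRECTIONS:
            raise ValueError("bits must have shape H x W x 8")

    @property
    def per_direction_counts(self) -> np.ndarray:
        return self.bits.sum(axis=(0, 1))

    @property
    def n_activated(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class IndexMatrix:
    """8x2 identity output of one activated neuron; one nonzero row."""

    rows: np.ndarray  # 8 x 2
    active_row: int

    @property
    def ix(self) -> float:
        return float(self.rows[self.active_row, 0])

    @property
    def iy(self) -> float:
        return float(self.rows[self.active_row, 1])


def _pixel_diff_exceeds(
    x: np.ndarray, y: np.ndarray, config: LMDNConfig, rgb: bool
) -> np.ndarray:
    """Boolean array: does |x - y| exceed L under the configured color rule?"""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rgb:
        if config.color_rule == "any_channel":
            return (np.abs(x - y) > config.threshold_L).any(axis=-1)
        x = x @ _LUMA
        y = y @ _LUMA
    return np.abs(x - y) > config.threshold_L


def bc_response(pair: FramePair, pos: tuple[int, int], config: LMDNConfig) -> int:
    """Bipolar bit: 1 iff the pixel value changed between the two frames."""
    r, c = pos
    h, w = pair.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"position {pos} outside {h}x{w} grid")
    return int(
        _pixel_diff_exceeds(
            pair.frame_t[r, c], pair.frame_t1[r, c], config, pair.color_mode == "rgb"
        )
    )


def hc_response(
    pair: FramePair,
    pos: tuple[int, int],
    offset: DirectionOffset,
    config: LMDNConfig,
) -> int:
    """Horizontal bit: compare this pixel at t with its directional neighbor at t+1.

    Returns 1 (inhibit) when the neighbor falls outside the grid, so border
    neurons cannot fire for motion pointing off the image.
    """
    r, c = pos
    h, w = pair.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"position {pos} outside {h}x{w} grid")
    nr, nc = r + offset.alpha, c + offset.beta
    if not (0 <= nr < h and 0 <= nc < w):
        return 1
    return int(
        _pixel_diff_exceeds(
            pair.frame_t[r, c], pair.frame_t1[nr, nc], config, pair.color_mode == "rgb"
        )
    )


def synapse(x: float, omega: float, theta: float, k: float) -> float:
    """Sigmoid synapse 1 / (1 + exp(-k (omega x - theta)))."""
    if k <= 0:
        raise ValueError("synapse steepness k must be > 0")
    return 1.0 / (1.0 + np.exp(-k * (omega * x - theta)))


def gc_output(bc: int, hc: int, config: LMDNConfig, mode: str = "hard") -> int:
    """Ganglion bit: excitatory BC AND-NOT inhibitory HC.

    ``soft`` mode routes both bits through sigmoid synapses and thresholds
    the product ``S(bc) * (1 - S(hc))``; with the default synapse parameters
    it matches the hard truth table on all four input combinations.
    """
    if bc not in (0, 1) or hc not in (0, 1):
        raise ValueError("bc and hc must be binary")
    if mode == "hard":
        return int(bc == 1 and hc == 0)
    if mode == "soft":
        s_bc = synapse(bc, config.synapse_omega, config.synapse_theta, config.synapse_k)
        s_hc = synapse(hc, config.synapse_omega, config.synapse_theta, config.synapse_k)
        return int(s_bc * (1.0 - s_hc) > config.gc_threshold)
    raise ValueError(f"unknown ganglion mode {mode!r}")


def lmdn_layer(pair: FramePair, config: LMDNConfig, mode: str = "hard") -> ActivationMap:
    """Evaluate all H*W*8 neurons on a frame pair (vectorized).

    For every pixel and direction d the neuron's bit is
    ``gc_output(bc_response, hc_response_d)``.
    """
    h, w = pair.shape
    rgb = pair.color_mode == "rgb"
    bc = _pixel_diff_exceeds(pair.frame_t, pair.frame_t1, config, rgb)
    bits = np.zeros((h, w, N_DIRECTIONS), dtype=bool)
    for d, (dr, dc) in enumerate(DIRECTION_OFFSETS):
        # neighbor values of frame_t1 shifted back onto the pixel grid;
        # off-grid neighbors inhibit unconditionally
        hc = np.ones((h, w), dtype=bool)
        rs = slice(max(0, -dr), h - max(0, dr))
        cs = slice(max(0, -dc), w - max(0, dc))
        rd = slice(max(0, dr), h + min(0, dr))
        cd = slice(max(0, dc), w + min(0, dc))
        hc[rs, cs] = _pixel_diff_exceeds(
            pair.frame_t[rs, cs], pair.frame_t1[rd, cd], config, rgb
        )
        if mode == "hard":
            bits[:, :, d] = bc & ~hc
        else:
            s_bc = synapse(
                bc.astype(float), config.synapse_omega, config.synapse_theta, config.synapse_k
            )
            s_hc = synapse(
                hc.astype(float), config.synapse_omega, config.synapse_theta, config.synapse_k
            )
            bits[:, :, d] = s_bc * (1.0 - s_hc) > config.gc_threshold
    return ActivationMap(bits)


def encode_index(row: int, col: int, d: int, config: LMDNConfig) -> IndexMatrix:
    """Identity matrix of the neuron at (row, col) preferring direction d.

    Row d holds (a + row, a + col); all other rows are zero.
    """
    if d < 0 or d >= N_DIRECTIONS:
        raise ValueError(f"direction must be in 0..7, got {d}")
    if row < 0 or col < 0:
        raise ValueError("row and col must be nonnegative")
    rows = np.zeros((N_DIRECTIONS, 2))
    rows[d] = (config.a + row, config.a + col)
    return IndexMatrix(rows, d)


def normalize_flatten(m: IndexMatrix, norm_const: float) -> np.ndarray:
    """Row-major flatten of the index matrix divided by ``norm_const``.

    The nonzero entries land at dimensions (2d, 2d+1) and lie in [0, 1] when
    ``norm_const`` is at least the largest possible index.
    """
    if norm_const <= 0:
        raise ValueError(f"norm_const must be positive, got {norm_const}")
    return m.rows.ravel() / norm_const


def activated_vectors(
    amap: ActivationMap, config: LMDNConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Index vectors of all activated neurons of an activation map.

    Returns ``(vectors, tags)`` where ``vectors`` is N x 16 and ``tags`` is
    N x 3 holding each neuron's (row, col, direction) ground truth.
    """
    h, w, _ = amap.bits.shape
    norm = config.resolve_norm_const(h, w)
    rows, cols, dirs = np.nonzero(amap.bits)
    n = rows.size
    vectors = np.zeros((n, 2 * N_DIRECTIONS))
    idx = np.arange(n)
    vectors[idx, 2 * dirs] = (config.a + rows) / norm
    vectors[idx, 2 * dirs + 1] = (config.a + cols) / norm
    return vectors, np.column_stack([rows, cols, dirs])
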