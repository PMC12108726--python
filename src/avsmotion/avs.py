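"""The two-layer artificial visual system (AVS).

Training is unsupervised: the Gaussian mixture clusters the index vectors of
the retinal neurons, and because every direction's vectors occupy a dedicated
pair of dimensions, a direction-pure clustering puts each component's mean
mass on exactly one dimension pair. Calibration reads that pair off the
fitted means to map each component label to its direction and angle — a
deterministic replacement for inspecting an embedding by eye.

Detection runs the retinal layer on a frame pair, encodes every activated
neuron's index vector, hard-assigns each to a mixture component, translates
component labels to directions, and reads the global motion direction as the
direction with the most activated neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .directions import N_DIRECTIONS, direction_angle
from .lmdn import ActivationMap, LMDNConfig, activated_vectors, lmdn_layer
from .mixture import GMMParams, GaussianMixtureEM
from .stimuli import FramePair, TrainingSet, enumerate_ideal_dataset

__all__ = [
    "LabelDirectionMap",
    "DetectionResult",
    "CalibrationError",
    "MotionDirectionAVS",
    "calibrate_labels",
    "train_avs",
    "detect",
]


class CalibrationError(RuntimeError):
    """The label-to-direction assignment is not a bijection (impure clustering)."""


@dataclass(frozen=True)
class LabelDirectionMap:
    """Bijection from mixture component labels to direction indices."""

    label_to_direction: tuple[int, ...]  # entry i = direction of label i

    def __post_init__(self) -> None:
        if sorted(self.label_to_direction) != list(range(N_DIRECTIONS)):
            raise CalibrationError(
                f"label map is not a bijection over the 8 directions: "
                f"{self.label_to_direction}"
            )

    def direction(self, label: int) -> int:
        return self.label_to_direction[label]

    def angle(self, label: int) -> float:
        return direction_angle(self.direction(label))

    def as_dict(self) -> dict[int, tuple[int, float]]:
        return {
            lab: (d, direction_angle(d))
            for lab, d in enumerate(self.label_to_direction)
        }


@dataclass
class DetectionResult:
    """Outcome of one detection: per-direction activation counts and the argmax."""

    global_direction: int | None
    per_direction_counts: np.ndarray  # 8 ints, indexed by direction
    per_label_counts: np.ndarray  # 8 ints, indexed by component label
    n_activated: int

    @property
    def angle(self) -> float | None:
        if self.global_direction is None:
            return None
        return direction_angle(self.global_direction)


def calibrate_labels(gmm_params: GMMParams) -> LabelDirectionMap:
    """Map each component to the direction whose dimension pair carries its mean.

    For component k, direction = argmax_j |mean_kj| // 2. Raises
    :class:`CalibrationError` when two components land on the same direction,
    which signals an impure clustering.
    """
    dirs = [int(np.argmax(np.abs(m)) // 2) for m in gmm_params.means]
    return LabelDirectionMap(tuple(dirs))


class MotionDirectionAVS(BaseEstimator):
    """Unsupervised motion-direction detector over 32x32 (by default) frames.

    ``fit`` trains the 8-component Gaussian mixture on neuron index vectors
    (the full ideal enumeration when no data is passed) and calibrates the
    label-to-direction map; ``detect`` / ``predict`` read out the global
    motion direction of frame pairs.

    Parameters
    ----------
    grid_shape : (H, W) of the retinal array.
    threshold_L, color_rule : retinal layer parameters (see LMDNConfig).
    a : index offset of the identity encoding.
    tol, max_iter, n_init, reg_eps, init_scheme : EM settings (see
        GaussianMixtureEM).
    random_state : seed for mixture initialization.

    Attributes
    ----------
    gmm_ : the fitted GaussianMixtureEM.
    label_map_ : calibrated LabelDirectionMap.
    cluster_sizes_ : vectors hard-assigned to each component during training.
    purity_ : fraction of training vectors whose component's majority truth
        direction matches their own (1.0 = direction-perfect clustering).
    """

    def __init__(
        self,
        grid_shape: tuple[int, int] = (32, 32),
        threshold_L: float = 0.0,
        color_rule: str = "any_channel",
        a: int = 16,
        tol: float = 1e-3,
        max_iter: int = 100,
        n_init: int = 10,
        reg_eps: float = 1e-6,
        init_scheme: str = "random_uniform",
        random_state: int | None = None,
        calibration_retries: int = 0,
    ):
        self.grid_shape = grid_shape
        self.threshold_L = threshold_L
        self.color_rule = color_rule
        self.a = a
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.reg_eps = reg_eps
        self.init_scheme = init_scheme
        self.random_state = random_state
        self.calibration_retries = calibration_retries

    @property
    def lmdn_config(self) -> LMDNConfig:
        return LMDNConfig(
            threshold_L=self.threshold_L, a=self.a, color_rule=self.color_rule
        )

    def fit(self, X: TrainingSet | np.ndarray | None = None, y=None) -> "MotionDirectionAVS":
        """Train the mixture on index vectors and calibrate the label map.

        ``X`` may be a :class:`TrainingSet`, a plain N x 16 matrix, or
        ``None`` to enumerate the full ideal dataset of ``grid_shape``.
        """
        h, w = self.grid_shape
        if X is None:
            X = enumerate_ideal_dataset(h, w, a=self.a)
        truth = X.truth_direction if isinstance(X, TrainingSet) else None
        vectors = X.vectors if isinstance(X, TrainingSet) else np.asarray(X, dtype=float)

        # The label map must be verified before the model can be used; when
        # retries are allowed, a non-bijective map triggers a refit with a
        # fresh (deterministically derived) restart stream.
        seeds = np.random.SeedSequence(self.random_state).spawn(
            self.calibration_retries + 1
        )
        for attempt, seed in enumerate(seeds):
            self.gmm_ = GaussianMixtureEM(
                n_components=N_DIRECTIONS,
                reg_eps=self.reg_eps,
                tol=self.tol,
                max_iter=self.max_iter,
                n_init=self.n_init,
                init_scheme=self.init_scheme,
                random_state=np.random.default_rng(seed),
            ).fit(vectors)
            labels = self.gmm_.labels_
            self.cluster_sizes_ = np.bincount(labels, minlength=N_DIRECTIONS)
            try:
                self.label_map_ = calibrate_labels(self.gmm_.params_)
                break
            except CalibrationError:
                if attempt == len(seeds) - 1:
                    raise CalibrationError(
                        "clustering is not direction-pure; per-cluster sizes: "
                        f"{self.cluster_sizes_.tolist()}"
                    ) from None
        if truth is not None:
            correct = 0
            for k in range(N_DIRECTIONS):
                member = truth[labels == k]
                if member.size:
                    correct += int(np.bincount(member).max())
            self.purity_ = correct / len(vectors)
        else:
            self.purity_ = None
        return self

    def detect(self, pair: FramePair) -> DetectionResult:
        """Full readout for one frame pair."""
        check_is_fitted(self, "gmm_")
        if pair.shape != tuple(self.grid_shape):
            raise ValueError(
                f"frame shape {pair.shape} does not match model grid {self.grid_shape}"
            )
        amap: ActivationMap = lmdn_layer(pair, self.lmdn_config)
        vectors, _tags = activated_vectors(amap, self.lmdn_config)
        per_label = np.zeros(N_DIRECTIONS, dtype=int)
        per_direction = np.zeros(N_DIRECTIONS, dtype=int)
        if len(vectors):
            labels = self.gmm_.predict(vectors)
            per_label = np.bincount(labels, minlength=N_DIRECTIONS)
            for lab, count in enumerate(per_label):
                per_direction[self.label_map_.direction(lab)] += count
        n_activated = int(per_label.sum())
        global_direction = int(np.argmax(per_direction)) if n_activated else None
        return DetectionResult(global_direction, per_direction, per_label, n_activated)

    def predict(self, pairs) -> np.ndarray:
        """Global direction per frame pair; -1 marks zero-activation stimuli."""
        if isinstance(pairs, FramePair):
            pairs = [pairs]
        out = np.empty(len(pairs), dtype=int)
        for i, pair in enumerate(pairs):
            d = self.detect(pair).global_direction
            out[i] = -1 if d is None else d
        return out


def train_avs(
    training_vectors: TrainingSet | None = None,
    seed: int | None = None,
    **config,
) -> MotionDirectionAVS:
    """Train an AVS on the given index vectors (ideal enumeration when None)."""
    return MotionDirectionAVS(random_state=seed, **config).fit(training_vectors)


def detect(pair: FramePair, model: MotionDirectionAVS) -> DetectionResult:
    """Functional wrapper over :meth:`MotionDirectionAVS.detect`."""
    return model.detect(pair)
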