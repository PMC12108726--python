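"""File formats: frame pairs (PNG / NPY stack), model bundles (NPZ), config (YAML)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .avs import LabelDirectionMap, MotionDirectionAVS
from .directions import N_DIRECTIONS
from .mixture import GaussianMixtureEM
from .stimuli import FramePair

__all__ = [
    "FormatError",
    "RunConfig",
    "read_frame_pair",
    "write_frame_pair",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


@dataclass
class RunConfig:
    """Serializable bundle of every tunable of a run."""

    grid_h: int = 32
    grid_w: int = 32
    a: int = 16
    norm_const: float | None = None
    threshold_L: float = 0.0
    color_rule: str = "any_channel"
    K: int = 8
    seed: int | None = None
    max_iter: int = 100
    tol: float = 1e-3
    n_init: int = 10
    reg_eps: float = 1e-6
    trials_per_cell: int = 800
    out_dir: str = "."

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path} does not hold a config mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.dtype == np.uint16:
        img = (img.astype(float) / 257.0).round().astype(np.uint8)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim == 3 and img.shape[2] not in (3,):
        raise FormatError(f"unsupported channel count {img.shape[2]} in {path}")
    return img


def read_frame_pair(path_a: str | Path, path_b: str | Path | None = None) -> FramePair:
    """Read a frame pair from two PNG files or one stacked ``.npy`` file.

    A stacked NPY holds an array of shape (2, H, W) or (2, H, W, 3).
    """
    path_a = Path(path_a)
    if path_b is None:
        if path_a.suffix.lower() != ".npy":
            raise FormatError("single-file frame pairs must be .npy stacks")
        stack = np.load(path_a)
        if stack.ndim not in (3, 4) or stack.shape[0] != 2:
            raise FormatError(
                f"stacked frame pair must be (2, H, W[, 3]), got {stack.shape}"
            )
        return FramePair(stack[0], stack[1])
    a, b = _load_image(path_a), _load_image(path_b)
    if a.shape != b.shape:
        raise FormatError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return FramePair(a, b)


def write_frame_pair(
    pair: FramePair, path_a: str | Path, path_b: str | Path | None = None
) -> None:
    """Write a frame pair to two PNGs, or one ``.npy`` stack if ``path_b`` is None."""
    path_a = Path(path_a)
    if path_b is None:
        if path_a.suffix.lower() != ".npy":
            raise FormatError("single-file frame pairs must be .npy stacks")
        np.save(path_a, np.stack([pair.frame_t, pair.frame_t1]))
        return
    import imageio.v3 as iio

    iio.imwrite(path_a, pair.frame_t.astype(np.uint8))
    iio.imwrite(path_b, pair.frame_t1.astype(np.uint8))


def save_model(model: MotionDirectionAVS, path: str | Path) -> None:
    """Serialize a trained AVS (mixture parameters, label map, retinal config)."""
    gmm = model.gmm_
    np.savez(
        path,
        version=MODEL_FORMAT_VERSION,
        grid_shape=np.asarray(model.grid_shape),
        a=model.a,
        threshold_L=model.threshold_L,
        color_rule=np.asarray(model.color_rule),
        weights=gmm.weights_,
        means=gmm.means_,
        covariances=gmm.covariances_,
        reg_eps=model.reg_eps,
        tol=model.tol,
        max_iter=model.max_iter,
        n_init=model.n_init,
        init_scheme=np.asarray(model.init_scheme),
        random_state=-1 if model.random_state is None else model.random_state,
        label_to_direction=np.asarray(model.label_map_.label_to_direction),
        loglik_trace=gmm.loglik_trace_,
        n_iter=gmm.n_iter_,
        converged=gmm.converged_,
        cluster_sizes=model.cluster_sizes_,
        purity=-1.0 if model.purity_ is None else model.purity_,
    )


def load_model(path: str | Path) -> MotionDirectionAVS:
    """Load a model bundle written by :func:`save_model`."""
    required = {
        "version", "grid_shape", "a", "threshold_L", "color_rule", "weights",
        "means", "covariances", "reg_eps", "label_to_direction",
    }
    with np.load(path, allow_pickle=False) as data:
        missing = required - set(data.files)
        if missing:
            raise FormatError(f"model file {path} is missing fields: {sorted(missing)}")
        version = int(data["version"])
        if version != MODEL_FORMAT_VERSION:
            raise FormatError(
                f"model format version {version} is not supported "
                f"(expected {MODEL_FORMAT_VERSION}); re-train or upgrade"
            )
        if len(data["weights"]) != N_DIRECTIONS:
            raise FormatError(
                f"model must have 8 components, found {len(data['weights'])}"
            )
        seed = int(data["random_state"])
        model = MotionDirectionAVS(
            grid_shape=tuple(int(v) for v in data["grid_shape"]),
            threshold_L=float(data["threshold_L"]),
            color_rule=str(data["color_rule"]),
            a=int(data["a"]),
            tol=float(data["tol"]),
            max_iter=int(data["max_iter"]),
            n_init=int(data["n_init"]),
            reg_eps=float(data["reg_eps"]),
            init_scheme=str(data["init_scheme"]),
            random_state=None if seed == -1 else seed,
        )
        gmm = GaussianMixtureEM(
            n_components=N_DIRECTIONS,
            reg_eps=float(data["reg_eps"]),
            tol=float(data["tol"]),
            max_iter=int(data["max_iter"]),
            n_init=int(data["n_init"]),
            init_scheme=str(data["init_scheme"]),
        )
        gmm.weights_ = data["weights"].copy()
        gmm.means_ = data["means"].copy()
        gmm.covariances_ = data["covariances"].copy()
        gmm.loglik_trace_ = data["loglik_trace"].copy()
        gmm.n_iter_ = int(data["n_iter"])
        gmm.converged_ = bool(data["converged"])
        gmm.lower_bound_ = float(gmm.loglik_trace_[-1]) if len(gmm.loglik_trace_) else np.nan
        model.gmm_ = gmm
        model.label_map_ = LabelDirectionMap(
            tuple(int(d) for d in data["label_to_direction"])
        )
        model.cluster_sizes_ = data["cluster_sizes"].copy()
        purity = float(data["purity"])
        model.purity_ = None if purity < 0 else purity
    return model
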