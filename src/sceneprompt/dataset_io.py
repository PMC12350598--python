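"""On-disk layout and run configuration for RGBD video datasets.

A dataset is a directory:

    rgb/%06d.png     8-bit RGB color frames
    depth/%06d.png   16-bit single-channel depth in integer millimeters
                     (0 = invalid / no return)
    masks/%06d.png   optional binary ground-truth masks, 0/255
    poses.json       optional list of {"index": i, "transform": 4x4 row-major}

In memory, depth is carried in meters as float64 and masks as boolean
arrays.  Frames are 0-indexed; pixel coordinates are (x right, y down)
with the origin at the top-left corner.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "RGBDFrame",
    "CameraPose",
    "VideoDataset",
    "Strategy",
    "RunConfig",
    "DatasetError",
    "ConfigError",
    "read_dataset",
    "write_dataset",
    "load_config",
]

# Names of the six monitored scene parameters (shared vocabulary with
# scene_monitor and reprompt_control).
SCENE_PARAMETERS = (
    "area_pct",
    "consistency_iou",
    "depth_mean_m",
    "depth_std_m",
    "cam_trans_m",
    "cam_rot_deg",
)

_ROT_TOL = 1e-6


class DatasetError(ValueError):
    """Structural or validation problem in an on-disk dataset."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RGBDFrame:
    """One aligned color+depth sample.

    ``rgb`` is H×W×3 uint8; ``depth`` is H×W float64 in meters with 0
    encoding an invalid return (time-of-flight dropout).
    """

    index: int
    rgb: np.ndarray
    depth: np.ndarray
    timestamp_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise DatasetError(f"negative frame index {self.index}")
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise DatasetError(f"rgb must be HxWx3, got {self.rgb.shape}")
        if self.depth.shape != self.rgb.shape[:2]:
            raise DatasetError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape} "
                "shapes differ"
            )
        if np.any(self.depth < 0):
            raise DatasetError("negative depth values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass(frozen=True)
class CameraPose:
    """Camera-to-world rigid transform for one frame."""

    index: int
    transform: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transform, dtype=float)
        if t.shape != (4, 4):
            raise DatasetError(f"pose must be 4x4, got {t.shape}")
        validate_rigid(t)
        object.__setattr__(self, "transform", t)

    @property
    def rotation(self) -> np.ndarray:
        return self.transform[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.transform[:3, 3]


def validate_rigid(t: np.ndarray, tol: float = _ROT_TOL) -> None:
    """Raise DatasetError unless ``t`` is a proper rigid transform."""
    if not np.allclose(t[3], [0.0, 0.0, 0.0, 1.0], atol=tol):
        raise DatasetError("pose last row is not (0,0,0,1)")
    r = t[:3, :3]
    if not np.allclose(r @ r.T, np.eye(3), atol=10 * tol):
        raise DatasetError("pose rotation is not orthonormal")
    if not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=1e-4):
        raise DatasetError("pose rotation determinant is not +1")


@dataclass
class VideoDataset:
    """An in-memory RGBD video with optional poses and ground truth."""

    frames: list[RGBDFrame]
    poses: Optional[list[CameraPose]] = None
    gt_masks: Optional[list[np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise DatasetError("dataset has no frames")
        indices = [f.index for f in self.frames]
        if len(set(indices)) != len(indices):
            raise DatasetError("duplicate frame indices")
        if self.poses is not None and len(self.poses) != len(self.frames):
            raise DatasetError("pose count does not match frame count")
        if self.gt_masks is not None and len(self.gt_masks) != len(self.frames):
            raise DatasetError("gt mask count does not match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Strategy:
    """Re-prompting policy selector.

    kind:
      - ``none``        never re-prompt (R_inf)
      - ``interval``    re-prompt every ``n`` frames (R_n; n=1 is per-frame)
      - ``scene_aware`` CUSUM detection on the named scene ``parameters``
                        with threshold factor ``alpha``
    """

    kind: str = "none"
    n: Optional[int] = None
    parameters: tuple[str, ...] = ()
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "interval", "scene_aware"):
            raise ConfigError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "interval":
            if self.n is None or self.n < 1:
                raise ConfigError(f"strategy.n must be >= 1, got {self.n}")
        if self.kind == "scene_aware":
            if self.alpha is None or self.alpha <= 0:
                raise ConfigError(f"strategy.alpha must be > 0, got {self.alpha}")
            if not self.parameters:
                raise ConfigError("strategy.parameters must be non-empty")
            for p in self.parameters:
                if p not in SCENE_PARAMETERS:
                    raise ConfigError(f"unknown scene parameter {p!r}")

    def label(self) -> str:
        if self.kind == "none":
            return "R_inf"
        if self.kind == "interval":
            return f"R_{self.n}"
        params = "+".join(self.parameters)
        return f"scene[{params}]a{self.alpha:g}"


#: Simulated per-stage inference latencies in milliseconds.  Defaults are
#: the measured single-GPU per-frame costs of the three reference models
#: (RGBD prompt generator, promptable segmenter, mask tracker).
DEFAULT_COST_MODEL = {
    "prompt_generator": 69.3,
    "segmenter": 428.4,
    "tracker": 84.1,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline run configuration with field defaults.

    Defaults: five-frame CUSUM window, slack factor k=0.5, candidate
    probability threshold 0.9 (strictly above), spacing factor f=0.1.
    """

    strategy: Strategy = field(default_factory=Strategy)
    window_w: int = 5
    k: float = 0.5
    prob_threshold: float = 0.9
    spacing_factor: float = 0.1
    cost_model: Optional[dict] = None
    force_reprompt_on_empty: bool = True
    backend: str = "calibrated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise ConfigError(f"window_w must be positive, got {self.window_w}")
        if self.k < 0:
            raise ConfigError(f"k must be non-negative, got {self.k}")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ConfigError(
                f"prob_threshold must lie in (0,1), got {self.prob_threshold}"
            )
        if self.spacing_factor <= 0:
            raise ConfigError(
                f"spacing_factor must be positive, got {self.spacing_factor}"
            )

    def with_strategy(self, strategy: Strategy) -> "RunConfig":
        return replace(self, strategy=strategy)


def _parse_strategy(raw) -> Strategy:
    if raw is None or raw == "none":
        return Strategy(kind="none")
    if isinstance(raw, str):
        if raw in ("interval", "scene_aware"):
            raise ConfigError(f"strategy {raw!r} requires a mapping with options")
        raise ConfigError(f"unknown strategy name {raw!r}")
    if not isinstance(raw, dict):
        raise ConfigError(f"strategy must be a name or mapping, got {type(raw)}")
    kind = raw.get("kind", "none")
    params = raw.get("parameters", ())
    if isinstance(params, str):
        params = (params,)
    return Strategy(
        kind=kind,
        n=raw.get("n"),
        parameters=tuple(params),
        alpha=raw.get("alpha"),
    )


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping, applying defaults."""
    data = dict(data or {})
    known = {
        "strategy",
        "window_w",
        "k",
        "prob_threshold",
        "spacing_factor",
        "cost_model",
        "force_reprompt_on_empty",
        "backend",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    if "strategy" in data:
        kwargs["strategy"] = _parse_strategy(data["strategy"])
    for key in known - {"strategy"}:
        if key in data and data[key] is not None:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    s = cfg.strategy
    strategy: object
    if s.kind == "none":
        strategy = "none"
    elif s.kind == "interval":
        strategy = {"kind": "interval", "n": s.n}
    else:
        strategy = {
            "kind": "scene_aware",
            "parameters": list(s.parameters),
            "alpha": s.alpha,
        }
    return {
        "strategy": strategy,
        "window_w": cfg.window_w,
        "k": cfg.k,
        "prob_threshold": cfg.prob_threshold,
        "spacing_factor": cfg.spacing_factor,
        "cost_model": cfg.cost_model,
        "force_reprompt_on_empty": cfg.force_reprompt_on_empty,
        "backend": cfg.backend,
        "seed": cfg.seed,
    }


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling unset fields with defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Dataset reader / writer
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _indexed_files(directory: Path) -> list[tuple[int, Path]]:
    out = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() != ".png":
            continue
        m = _NUM_RE.search(p.stem)
        if m is None:
            raise DatasetError(f"filename without frame number: {p}")
        out.append((int(m.group(1)), p))
    out.sort(key=lambda t: t[0])
    return out


def _read_image(path: Path) -> np.ndarray:
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise DatasetError(f"unreadable image {path}: {exc}") from exc


def read_dataset(path) -> VideoDataset:
    """Read a dataset directory into memory.

    Depth is converted from stored integer millimeters to meters.  Missing
    ``poses.json`` or ``masks/`` simply leave the optional fields absent.
    """
    root = Path(path)
    rgb_dir, depth_dir = root / "rgb", root / "depth"
    if not rgb_dir.is_dir() or not depth_dir.is_dir():
        raise DatasetError(f"{root} must contain rgb/ and depth/ subdirectories")
    rgb_files = _indexed_files(rgb_dir)
    depth_files = _indexed_files(depth_dir)
    if len(rgb_files) != len(depth_files):
        raise DatasetError(
            f"rgb has {len(rgb_files)} frames but depth has {len(depth_files)}"
        )
    frames = []
    for (ri, rp), (di, dp) in zip(rgb_files, depth_files):
        if ri != di:
            raise DatasetError(f"frame index mismatch: rgb {ri} vs depth {di}")
        rgb = _read_image(rp)
        depth_mm = _read_image(dp)
        if depth_mm.ndim != 2:
            raise DatasetError(f"depth image {dp} is not single-channel")
        frames.append(
            RGBDFrame(index=ri, rgb=rgb.astype(np.uint8),
                      depth=depth_mm.astype(np.float64) / 1000.0)
        )

    poses = None
    pose_path = root / "poses.json"
    if pose_path.exists():
        raw = json.loads(pose_path.read_text())
        poses = [
            CameraPose(index=item["index"], transform=np.asarray(item["transform"]))
            for item in raw
        ]
        poses.sort(key=lambda p: p.index)
        if [p.index for p in poses] != [f.index for f in frames]:
            raise DatasetError("pose indices do not match frame indices")

    gt_masks = None
    mask_dir = root / "masks"
    if mask_dir.is_dir():
        mask_files = _indexed_files(mask_dir)
        if [i for i, _ in mask_files] != [f.index for f in frames]:
            raise DatasetError("mask indices do not match frame indices")
        gt_masks = [_read_image(p) > 127 for _, p in mask_files]

    meta_path = root / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    meta.setdefault("resolution", list(frames[0].shape))
    meta.setdefault("n_frames", len(frames))
    return VideoDataset(frames=frames, poses=poses, gt_masks=gt_masks, meta=meta)


def write_dataset(ds: VideoDataset, path, overwrite: bool = False) -> dict:
    """Write a dataset to ``path`` in the standard layout; return a manifest.

    Depth is quantized to nearest-integer millimeters (uint16).
    """
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise DatasetError(f"refusing to write into non-empty directory {root}")
    (root / "rgb").mkdir(parents=True, exist_ok=True)
    (root / "depth").mkdir(exist_ok=True)
    if ds.gt_masks is not None:
        (root / "masks").mkdir(exist_ok=True)

    for i, frame in enumerate(ds.frames):
        name = f"{frame.index:06d}.png"
        iio.imwrite(root / "rgb" / name, frame.rgb)
        depth_mm = np.rint(frame.depth * 1000.0).astype(np.uint16)
        iio.imwrite(root / "depth" / name, depth_mm)
        if ds.gt_masks is not None:
            mask = (ds.gt_masks[i].astype(np.uint8)) * 255
            iio.imwrite(root / "masks" / name, mask)

    if ds.poses is not None:
        payload = [
            {"index": p.index, "transform": p.transform.tolist()} for p in ds.poses
        ]
        (root / "poses.json").write_text(json.dumps(payload))
    if ds.meta:
        (root / "meta.json").write_text(json.dumps(_jsonable(ds.meta)))

    return {
        "path": str(root),
        "n_frames": len(ds),
        "resolution": list(ds.shape),
        "has_poses": ds.poses is not None,
        "has_masks": ds.gt_masks is not None,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_masks(masks: Sequence[np.ndarray], indices: Sequence[int], path) -> None:
    """Write predicted binary masks in the dataset mask format."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for mask, idx in zip(masks, indices):
        iio.imwrite(root / f"{idx:06d}.png", mask.astype(np.uint8) * 255)


def read_masks(path) -> tuple[list[np.ndarray], list[int]]:
    """Read a directory of binary mask PNGs; returns (masks, indices)."""
    files = _indexed_files(Path(path))
    if not files:
        raise DatasetError(f"no mask files in {path}")
    return [_read_image(p) > 127 for _, p in files], [i for i, _ in files]
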