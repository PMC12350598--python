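"""Per-frame scene parameters monitored for re-prompting.

Six streams are tracked: segmented-area size (percent of the image),
frame-to-frame mask consistency (IoU), mean and standard deviation of
depth within the mask (meters, invalid returns excluded), and camera
translation (meters) / rotation (degrees) between consecutive poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset_io import SCENE_PARAMETERS, CameraPose, RGBDFrame, validate_rigid

__all__ = [
    "SceneSample",
    "area_fraction",
    "iou",
    "depth_stats",
    "camera_motion",
    "sample_scene",
    "samples_to_frame",
]


@dataclass(frozen=True)
class SceneSample:
    """Monitored parameter values for one frame, with per-parameter validity."""

    index: int
    values: dict = field(default_factory=dict)
    validity: dict = field(default_factory=dict)

    def valid(self, name: str) -> bool:
        return bool(self.validity.get(name, False))

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def area_fraction(mask: np.ndarray) -> float:
    """Segmented area as a percentage of the image."""
    mask = np.asarray(mask, dtype=bool)
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Two empty masks agree perfectly (IoU 1, "no change"); exactly one
    empty mask gives 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b)) / union


def depth_stats(depth: np.ndarray, mask: np.ndarray) -> tuple[float, float, bool]:
    """(mean, population std, valid) of depth inside the mask.

    Depth 0 encodes a missing time-of-flight return and is excluded.
    ``valid`` is False when the mask holds no valid depth pixel.
    """
    depth = np.asarray(depth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if depth.shape != mask.shape:
        raise ValueError(f"shapes differ: {depth.shape} vs {mask.shape}")
    vals = depth[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0.0, 0.0, False
    return float(vals.mean()), float(vals.std(ddof=0)), True


def camera_motion(p_prev: CameraPose, p_cur: CameraPose) -> tuple[float, float]:
    """Relative camera movement between consecutive frames.

    Translation is the Euclidean norm of the relative displacement in
    meters; rotation is the geodesic angle of the relative rotation in
    degrees.  Both are invariant under a common rigid change of the
    world frame.
    """
    a, b = p_prev.transform, p_cur.transform
    validate_rigid(a)
    validate_rigid(b)
    rel = np.linalg.inv(a) @ b
    trans = float(np.linalg.norm(rel[:3, 3]))
    cos_angle = (np.trace(rel[:3, :3]) - 1.0) / 2.0
    rot = float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
    return trans, rot


def sample_scene(
    frame: RGBDFrame,
    mask: np.ndarray,
    prev_mask: Optional[np.ndarray] = None,
    pose: Optional[CameraPose] = None,
    prev_pose: Optional[CameraPose] = None,
) -> SceneSample:
    """Assemble all six monitored parameters for one frame.

    Consistency and camera parameters are invalid on the first frame
    after (re-)initialization, when no predecessor exists.
    """
    values = {name: 0.0 for name in SCENE_PARAMETERS}
    validity = {name: False for name in SCENE_PARAMETERS}

    values["area_pct"] = area_fraction(mask)
    validity["area_pct"] = True

    mean_m, std_m, depth_valid = depth_stats(frame.depth, mask)
    values["depth_mean_m"], values["depth_std_m"] = mean_m, std_m
    validity["depth_mean_m"] = validity["depth_std_m"] = depth_valid

    if prev_mask is not None:
        values["consistency_iou"] = iou(prev_mask, mask)
        validity["consistency_iou"] = True

    if pose is not None and prev_pose is not None:
        trans, rot = camera_motion(prev_pose, pose)
        values["cam_trans_m"], values["cam_rot_deg"] = trans, rot
        validity["cam_trans_m"] = validity["cam_rot_deg"] = True

    return SceneSample(index=frame.index, values=values, validity=validity)


def samples_to_frame(samples: list[SceneSample]) -> pd.DataFrame:
    """Scene-sample stream as a tidy table (one row per frame) for replay."""
    rows = []
    for s in samples:
        row: dict = {"index": s.index}
        for name in SCENE_PARAMETERS:
            row[name] = s.values.get(name, np.nan)
            row[f"{name}_valid"] = s.valid(name)
        rows.append(row)
    return pd.DataFrame(rows)
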