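"""Pluggable model contracts and deterministic reference mocks.

The pipeline needs three perception roles: an RGBD *prompt generator*
producing a per-pixel foreground probability map, a *promptable
segmenter* turning point prompts into a binary mask, and a
*semi-supervised tracker* propagating a reference mask through
subsequent frames.  The contracts below are what a real-model adapter
must implement; the mock implementations read synthetic ground truth and
degrade it in controlled, seeded ways, so the orchestration and
re-prompting control — the testable core of the artifact — can be
exercised without any neural network.

All mock randomness is keyed by (seed, frame index), never by call
order, so identical frames always produce identical outputs regardless
of the policy that requested them.

Adapter plug-in point: subclass the three contracts, register a factory
with :func:`register_backend`, and select it by name in the run
configuration.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .dataset_io import DEFAULT_COST_MODEL, RGBDFrame
from .prompting import PromptSet
from .scene_monitor import area_fraction

__all__ = [
    "PromptGenerator",
    "Segmenter",
    "Tracker",
    "BackendSet",
    "TrackerStateError",
    "OraclePromptGenerator",
    "OracleSegmenter",
    "DriftingTracker",
    "register_backend",
    "make_backend_set",
    "BACKEND_REGISTRY",
]


class TrackerStateError(RuntimeError):
    """Tracker used before initialization."""


# ---------------------------------------------------------------------------
# Contracts
# ---------------------------------------------------------------------------


class PromptGenerator(abc.ABC):
    """RGBD frame -> per-pixel foreground probability in [0, 1]."""

    latency_ms: float = DEFAULT_COST_MODEL["prompt_generator"]

    @abc.abstractmethod
    def predict(self, frame: RGBDFrame) -> np.ndarray: ...


class Segmenter(abc.ABC):
    """(frame, point prompts) -> binary mask at the frame's resolution.

    Implementations may resize internally (e.g. to a fixed 1024 input
    grid); the returned mask must match the original resolution.
    """

    latency_ms: float = DEFAULT_COST_MODEL["segmenter"]

    @abc.abstractmethod
    def segment(self, frame: RGBDFrame, prompts: PromptSet) -> np.ndarray: ...


class Tracker(abc.ABC):
    """Reference-mask initialization followed by per-frame propagation."""

    latency_ms: float = DEFAULT_COST_MODEL["tracker"]

    @abc.abstractmethod
    def initialize(self, frame: RGBDFrame, reference_mask: np.ndarray) -> None: ...

    @abc.abstractmethod
    def update(self, frame: RGBDFrame) -> np.ndarray: ...


@dataclass
class BackendSet:
    prompt_generator: PromptGenerator
    segmenter: Segmenter
    tracker: Tracker

    def apply_cost_model(self, cost_model: Optional[dict]) -> None:
        if not cost_model:
            return
        self.prompt_generator.latency_ms = cost_model.get(
            "prompt_generator", self.prompt_generator.latency_ms
        )
        self.segmenter.latency_ms = cost_model.get(
            "segmenter", self.segmenter.latency_ms
        )
        self.tracker.latency_ms = cost_model.get("tracker", self.tracker.latency_ms)


def _frame_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(stream, index))
    )


def _shift_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-shift a boolean mask with zero fill (x right, y down)."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    if abs(dx) >= w or abs(dy) >= h:
        return out
    sy0, sy1 = max(0, -dy), min(h, h - dy)
    sx0, sx1 = max(0, -dx), min(w, w - dx)
    out[sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx] = mask[sy0:sy1, sx0:sx1]
    return out


# ---------------------------------------------------------------------------
# Mocks
# ---------------------------------------------------------------------------


class OraclePromptGenerator(PromptGenerator):
    """Probability-map oracle with controllable boundary error.

    Emits probability 0.95 inside a jittered copy of the ground-truth
    silhouette and 0.05 outside; with rate ``false_region_rate`` a
    spurious high-probability blob appears away from the object,
    emulating the false positives of a fast fully-supervised RGBD
    segmenter.
    """

    def __init__(
        self,
        gt_masks: Sequence[np.ndarray],
        boundary_jitter_px: int = 0,
        false_region_rate: float = 0.0,
        seed: int = 0,
        p_in: float = 0.95,
        p_out: float = 0.05,
    ) -> None:
        self.gt_masks = gt_masks
        self.jitter = int(boundary_jitter_px)
        self.false_region_rate = float(false_region_rate)
        self.seed = int(seed)
        self.p_in, self.p_out = p_in, p_out

    def predict(self, frame: RGBDFrame) -> np.ndarray:
        gt = np.asarray(self.gt_masks[frame.index], dtype=bool)
        rng = _frame_rng(self.seed, frame.index, stream=10)
        mask = gt
        if self.jitter > 0:
            dx, dy = rng.integers(-self.jitter, self.jitter + 1, size=2)
            mask = _shift_mask(mask, int(dx), int(dy))
            grow = int(rng.integers(-self.jitter, self.jitter + 1))
            if grow > 0:
                mask = ndimage.binary_dilation(mask, iterations=grow)
            elif grow < 0:
                mask = ndimage.binary_erosion(mask, iterations=-grow)
        prob = np.where(mask, self.p_in, self.p_out)
        if self.false_region_rate > 0 and rng.random() < self.false_region_rate:
            h, w = gt.shape
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = int(rng.integers(6, 14))
            yy, xx = np.ogrid[0:h, 0:w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            prob = np.where(blob & ~gt, self.p_in, prob)
        return prob


class OracleSegmenter(Segmenter):
    """Segmentation oracle calibrated to a target IoU against ground truth.

    The ground-truth silhouette is eroded or dilated (choice and exact
    level seeded per frame) along its Euclidean distance transform until
    the overlap with ground truth lands within ±0.05 of ``iou_target``.
    Prompts falling outside the object add a small spurious component,
    modeling prompt-quality sensitivity.
    """

    def __init__(
        self,
        gt_masks: Sequence[np.ndarray],
        iou_target: float = 0.85,
        seed: int = 0,
    ) -> None:
        if not (0.0 < iou_target <= 1.0):
            raise ValueError(f"iou_target must lie in (0,1], got {iou_target}")
        self.gt_masks = gt_masks
        self.iou_target = float(iou_target)
        self.seed = int(seed)

    def segment(self, frame: RGBDFrame, prompts: PromptSet) -> np.ndarray:
        if len(prompts) == 0:
            raise ValueError("segmenter requires at least one prompt")
        gt = np.asarray(self.gt_masks[frame.index], dtype=bool)
        if self.iou_target >= 1.0 or not gt.any():
            out = gt.copy()
        else:
            rng = _frame_rng(self.seed, frame.index, stream=20)
            target = float(
                np.clip(self.iou_target + rng.uniform(-0.03, 0.03), 0.05, 1.0)
            )
            if rng.random() < 0.5:
                out = self._erode_to(gt, target)
            else:
                out = self._dilate_to(gt, target)
        outside = [p for p in prompts.points if not gt[p[1], p[0]]]
        if outside and self.iou_target < 1.0:
            x, y = outside[0]
            h, w = gt.shape
            yy, xx = np.ogrid[0:h, 0:w]
            blob = (yy - y) ** 2 + (xx - x) ** 2 <= 6**2
            out = out | (blob & ~gt)
        return out

    @staticmethod
    def _erode_to(gt: np.ndarray, target: float) -> np.ndarray:
        # iou(eroded, gt) = |eroded| / |gt|: keep the innermost target share.
        dt = ndimage.distance_transform_edt(gt)
        vals = np.sort(dt[gt])
        n = vals.size
        cut = vals[min(n - 1, int(round((1.0 - target) * n)))]
        hi, lo = dt > cut, dt >= cut
        n_hi, n_lo = int(hi.sum()), int(lo.sum())
        want = target * n
        return hi if abs(n_hi - want) <= abs(n_lo - want) else lo

    @staticmethod
    def _dilate_to(gt: np.ndarray, target: float) -> np.ndarray:
        # iou(gt, dilated) = |gt| / |dilated|: grow outward to |gt|/target.
        dt = ndimage.distance_transform_edt(~gt)
        n_gt = int(gt.sum())
        extra = int(round(n_gt * (1.0 / target - 1.0)))
        outside = np.sort(dt[~gt & (dt > 0)])
        if extra <= 0 or outside.size == 0:
            return gt.copy()
        cut = outside[min(outside.size - 1, extra - 1)]
        lo, hi = gt | (dt <= cut), gt | (dt < cut)
        want = n_gt + extra
        n_lo, n_hi = int(lo.sum()), int(hi.sum())
        return lo if abs(n_lo - want) <= abs(n_hi - want) else hi


class DriftingTracker(Tracker):
    """Mask propagator whose quality decays with frames since initialization.

    The internal mask is the reference mask translated by a seeded drift
    whose displacement grows at ``decay_per_frame`` of the object's
    equivalent radius per frame (so the IoU against a static target
    falls at roughly that relative rate), plus one-pixel boundary noise.
    Frames where the ground-truth area jumps by more than 10% (occlusion
    onsets/offsets) inject extra drift scaled by
    ``occlusion_sensitivity``.  Re-initialization restores the provided
    reference mask exactly.
    """

    def __init__(
        self,
        gt_masks: Sequence[np.ndarray],
        decay_per_frame: float = 0.01,
        occlusion_sensitivity: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.gt_masks = gt_masks
        self.decay = float(decay_per_frame)
        self.occ_sens = float(occlusion_sensitivity)
        self.seed = int(seed)
        self._ref: Optional[np.ndarray] = None
        self._offset = np.zeros(2)
        self._init_index: Optional[int] = None
        self._prev_gt_area: Optional[float] = None

    def initialize(self, frame: RGBDFrame, reference_mask: np.ndarray) -> None:
        self._ref = np.asarray(reference_mask, dtype=bool).copy()
        self._offset = np.zeros(2)
        self._init_index = frame.index
        self._prev_gt_area = area_fraction(self.gt_masks[frame.index])

    def update(self, frame: RGBDFrame) -> np.ndarray:
        if self._ref is None:
            raise TrackerStateError("tracker.update called before initialize")
        if self.decay == 0.0:
            return self._ref.copy()
        rng = _frame_rng(self.seed, frame.index, stream=30)
        n_ref = int(self._ref.sum())
        r_eq = float(np.sqrt(max(n_ref, 1) / np.pi))
        # Direction biased by the initialization seed: displacement grows
        # roughly linearly, not as a sqrt(t) random walk.
        bias_rng = _frame_rng(self.seed, int(self._init_index or 0), stream=31)
        bias_ang = bias_rng.uniform(0, 2 * np.pi)
        ang = bias_ang + rng.normal(0.0, 0.6)
        step = self.decay * r_eq
        gt_area = area_fraction(self.gt_masks[frame.index])
        if self._prev_gt_area is not None and self._prev_gt_area > 0:
            rel_change = abs(gt_area - self._prev_gt_area) / self._prev_gt_area
            if rel_change > 0.10:
                step *= 1.0 + 4.0 * self.occ_sens
        self._prev_gt_area = gt_area
        self._offset += step * np.array([np.cos(ang), np.sin(ang)])
        out = _shift_mask(
            self._ref, int(round(self._offset[0])), int(round(self._offset[1]))
        )
        # Boundary noise: one-pixel breathing of the propagated contour.
        if out.any():
            if rng.random() < 0.5:
                out = ndimage.binary_dilation(out)
            else:
                out = ndimage.binary_erosion(out)
        return out


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

BACKEND_REGISTRY: dict[str, Callable[..., BackendSet]] = {}


def register_backend(name: str, factory: Callable[..., BackendSet]) -> None:
    BACKEND_REGISTRY[name] = factory


def _noiseless(gt_masks, seed: int = 0) -> BackendSet:
    return BackendSet(
        prompt_generator=OraclePromptGenerator(gt_masks, 0, 0.0, seed),
        segmenter=OracleSegmenter(gt_masks, iou_target=1.0, seed=seed),
        tracker=DriftingTracker(gt_masks, decay_per_frame=0.0, seed=seed),
    )


def _calibrated(gt_masks, seed: int = 0) -> BackendSet:
    """Default noisy mocks: boundary error on the prompt map, segmenter
    near IoU 0.85, tracker decaying at 1% of the object radius per frame."""
    return BackendSet(
        prompt_generator=OraclePromptGenerator(
            gt_masks, boundary_jitter_px=2, false_region_rate=0.05, seed=seed
        ),
        segmenter=OracleSegmenter(gt_masks, iou_target=0.85, seed=seed),
        tracker=DriftingTracker(
            gt_masks, decay_per_frame=0.01, occlusion_sensitivity=1.0, seed=seed
        ),
    )


register_backend("noiseless", _noiseless)
register_backend("calibrated", _calibrated)


def make_backend_set(name: str, gt_masks, seed: int = 0) -> BackendSet:
    """Instantiate a registered backend set against a ground-truth sequence."""
    try:
        factory = BACKEND_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered: {sorted(BACKEND_REGISTRY)}"
        ) from None
    return factory(gt_masks, seed=seed)
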