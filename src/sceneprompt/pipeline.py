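"""Pipeline orchestration: prompt -> segment -> track, with re-prompting.

At the start frame the prompt generator's probability map is thresholded
into candidates, spaced into point prompts, segmented into a reference
mask, and the tracker is initialized with it.  Every later frame is
propagated by the tracker; the resulting mask (before any correction)
feeds the scene monitor, whose sample drives the configured re-prompting
policy.  On a trigger the whole prompt/segment stage re-runs on the
*current* frame and the tracker is re-initialized with the fresh mask —
detection implies immediate correction.  A re-prompt attempt that finds
no candidate pixels keeps the tracker's mask, records the failure, and
resets the detector so degenerate scenes do not trigger storms.

Per-frame cost is either measured wall-clock or, with a cost model,
the sum of the declared latencies of the stages that actually executed
— the segmenter is only charged on frames where it ran, which is the
whole point of re-prompting only when necessary.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .backends import BackendSet
from .dataset_io import RunConfig, VideoDataset
from .prompting import EmptyCandidateError, prompts_from_probability
from .reprompt_control import (
    CusumChannel,
    RepromptDecision,
    interval_step,
    scene_aware_step,
)
from .scene_monitor import SceneSample, sample_scene

__all__ = ["FrameResult", "RepromptEvent", "run", "simulated_fps"]


@dataclass
class FrameResult:
    """Mask, provenance and cost for one processed frame."""

    index: int
    mask: np.ndarray
    source: str  # segmenter | tracker | carried_over
    decision: RepromptDecision
    time_ms: float
    prompt_count: Optional[int] = None
    sample: Optional[SceneSample] = None


@dataclass(frozen=True)
class RepromptEvent:
    index: int
    outcome: str  # applied | failed_empty_candidates
    reason: str
    channel: Optional[str] = None


def run(
    ds: VideoDataset,
    backends: BackendSet,
    cfg: RunConfig,
    start_frame: int = 0,
) -> tuple[list[FrameResult], list[RepromptEvent]]:
    """Execute the pipeline from ``start_frame`` to the end of the video."""
    n = len(ds)
    if not (0 <= start_frame < n):
        raise ValueError(f"start_frame {start_frame} outside video of {n} frames")
    strategy = cfg.strategy
    simulated = cfg.cost_model is not None
    if simulated:
        backends.apply_cost_model(cfg.cost_model)
    pg, seg, trk = backends.prompt_generator, backends.segmenter, backends.tracker

    channels: list[CusumChannel] = []
    if strategy.kind == "scene_aware":
        channels = [
            CusumChannel(name=p, window_w=cfg.window_w, k=cfg.k,
                         alpha=float(strategy.alpha))
            for p in strategy.parameters
        ]

    results: list[FrameResult] = []
    events: list[RepromptEvent] = []
    empty = np.zeros(ds.shape, dtype=bool)
    prev_mask: Optional[np.ndarray] = None
    prev_pose = None
    last_prompt_index = start_frame
    tracker_ready = False

    def attempt_prompt(i, frame, cost_box) -> tuple[Optional[np.ndarray], int]:
        """Run prompt generation + segmentation; None on empty candidates."""
        prob = pg.predict(frame)
        cost_box[0] += pg.latency_ms
        try:
            prompts = prompts_from_probability(
                prob, cfg.prob_threshold, cfg.spacing_factor, source_frame=i
            )
        except EmptyCandidateError:
            return None, 0
        mask = seg.segment(frame, prompts)
        cost_box[0] += seg.latency_ms
        trk.initialize(frame, mask)
        return mask, len(prompts)

    for i in range(start_frame, n):
        frame = ds.frames[i]
        pose = ds.poses[i] if ds.poses is not None else None
        wall_start = time.perf_counter()
        cost = [0.0]
        reinitialized = False
        prompt_count: Optional[int] = None

        if i == start_frame:
            decision = RepromptDecision(index=i, triggered=False)
            cost[0] += trk.latency_ms
            mask, count = attempt_prompt(i, frame, cost)
            if mask is None:
                mask = empty
                source = "carried_over"
                events.append(RepromptEvent(i, "failed_empty_candidates", "start"))
            else:
                source = "segmenter"
                prompt_count = count
                reinitialized = True
        else:
            if tracker_ready:
                mask = trk.update(frame)
                source = "tracker"
                cost[0] += trk.latency_ms
            else:  # start-frame prompting failed and never recovered
                mask = prev_mask if prev_mask is not None else empty
                source = "carried_over"

            sample = sample_scene(frame, mask, prev_mask, pose, prev_pose)
            if strategy.kind == "interval":
                decision = interval_step(
                    strategy.n, i - last_prompt_index, index=i
                )
            elif strategy.kind == "scene_aware":
                decision = scene_aware_step(channels, sample)
            else:
                decision = RepromptDecision(index=i, triggered=False)

            if (
                not decision.triggered
                and cfg.force_reprompt_on_empty
                and not mask.any()
            ):
                decision = RepromptDecision(
                    index=i, triggered=True, reason="empty_mask"
                )

            if decision.triggered:
                new_mask, count = attempt_prompt(i, frame, cost)
                last_prompt_index = i
                for ch in channels:
                    ch.reset()
                if new_mask is None:
                    events.append(
                        RepromptEvent(i, "failed_empty_candidates",
                                      decision.reason, decision.trigger_channel)
                    )
                else:
                    mask = new_mask
                    source = "segmenter"
                    prompt_count = count
                    reinitialized = True
                    events.append(
                        RepromptEvent(i, "applied", decision.reason,
                                      decision.trigger_channel)
                    )

        if simulated:
            time_ms = cost[0]
        else:
            time_ms = (time.perf_counter() - wall_start) * 1000.0

        sample_out = None
        if i != start_frame:
            sample_out = sample  # monitored values before any correction
        results.append(
            FrameResult(index=i, mask=mask, source=source, decision=decision,
                        time_ms=time_ms, prompt_count=prompt_count,
                        sample=sample_out)
        )

        if reinitialized:
            tracker_ready = True
            # Consistency/camera streams restart after (re-)initialization.
            prev_mask, prev_pose = None, None
        else:
            prev_mask, prev_pose = mask, pose

    return results, events


def simulated_fps(results: list[FrameResult]) -> float:
    """Average frame rate implied by the per-frame costs: 1000*n/sum(ms)."""
    if not results:
        raise ValueError("no frame results")
    total = float(sum(r.time_ms for r in results))
    if total <= 0:
        raise ValueError("total processing time is zero")
    return 1000.0 * len(results) / total
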