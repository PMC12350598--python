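"""Scoring, multi-start aggregation, parameter sweeps and statistics.

A run is scored by per-frame IoU against ground truth (median first,
mean ± sd secondary), its simulated or measured FPS, and the share of
frames on which a re-prompt was applied.  To reduce the influence of the
initial frame, each configuration is evaluated from five start frames
spaced 25 frames apart and the per-frame IoUs are pooled.  Strategies
are compared with the two-sided Wilcoxon matched-pairs signed-rank test
on paired per-frame IoU sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .backends import BackendSet
from .dataset_io import RunConfig, Strategy, VideoDataset
from .pipeline import FrameResult, RepromptEvent, run, simulated_fps
from .scene_monitor import iou

__all__ = [
    "EvalRecord",
    "SweepResult",
    "ComparisonResult",
    "evaluate_run",
    "multi_start_evaluate",
    "pooled_iou",
    "sweep",
    "compare_strategies",
    "tradeoff_plot",
]

#: Interval settings of the standard sweep, widest first.
SWEEP_INTERVALS = (50, 40, 30, 20, 10)
#: Threshold factors of the standard scene-aware sweep.
SWEEP_ALPHAS = (2.0, 4.0, 6.0, 8.0, 10.0)
#: Monitored-parameter sets: each singleton plus size+consistency combined.
SWEEP_PARAMETER_SETS = (
    ("area_pct",),
    ("consistency_iou",),
    ("depth_mean_m",),
    ("depth_std_m",),
    ("cam_trans_m",),
    ("cam_rot_deg",),
    ("area_pct", "consistency_iou"),
)


@dataclass
class EvalRecord:
    """Aggregated score of one pipeline run."""

    per_frame_iou: np.ndarray
    median_iou: float
    mean_iou: float
    iou_sd: float
    fps: float
    reprompt_fraction: float
    strategy: str = ""
    start_frame: int = 0
    seed: int = 0

    def as_row(self) -> dict:
        return {
            "strategy": self.strategy,
            "start_frame": self.start_frame,
            "seed": self.seed,
            "median_iou": self.median_iou,
            "mean_iou": self.mean_iou,
            "iou_sd": self.iou_sd,
            "fps": self.fps,
            "reprompt_fraction": self.reprompt_fraction,
            "n_frames": len(self.per_frame_iou),
        }


@dataclass
class SweepResult:
    records: list[EvalRecord] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        """Trade-off table, one row per (strategy, start), sorted by FPS."""
        df = pd.DataFrame([r.as_row() for r in self.records])
        return df.sort_values("fps", ascending=False).reset_index(drop=True)

    def aggregate(self) -> pd.DataFrame:
        """Mean over start frames per strategy, sorted by FPS."""
        df = pd.DataFrame([r.as_row() for r in self.records])
        agg = df.groupby("strategy", as_index=False).agg(
            median_iou=("median_iou", "mean"),
            mean_iou=("mean_iou", "mean"),
            fps=("fps", "mean"),
            reprompt_fraction=("reprompt_fraction", "mean"),
        )
        return agg.sort_values("fps", ascending=False).reset_index(drop=True)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def evaluate_run(
    results: Sequence[FrameResult],
    gt_masks: Sequence[np.ndarray],
    events: Optional[Sequence[RepromptEvent]] = None,
    strategy: str = "",
    seed: int = 0,
) -> EvalRecord:
    """Score one run against ground truth.

    ``gt_masks`` is the full video ground truth; each result is matched
    by its frame index.  Frames before the run's start frame are thereby
    excluded automatically.
    """
    if not results:
        raise ValueError("no frame results to evaluate")
    if max(r.index for r in results) >= len(gt_masks):
        raise ValueError(
            f"results reference frame {max(r.index for r in results)} but only "
            f"{len(gt_masks)} ground-truth masks are available"
        )
    ious = np.array([iou(r.mask, gt_masks[r.index]) for r in results])
    if events is not None:
        applied = sum(1 for e in events if e.outcome == "applied")
    else:
        applied = sum(
            1
            for r in results
            if r.source == "segmenter" and r.decision.triggered
        )
    return EvalRecord(
        per_frame_iou=ious,
        median_iou=float(np.median(ious)),
        mean_iou=float(ious.mean()),
        iou_sd=float(ious.std(ddof=0)),
        fps=simulated_fps(list(results)),
        reprompt_fraction=applied / len(results),
        strategy=strategy,
        start_frame=results[0].index,
        seed=seed,
    )


def multi_start_evaluate(
    ds: VideoDataset,
    make_backends: Callable[[], BackendSet],
    cfg: RunConfig,
    n_starts: int = 5,
    stride: int = 25,
    first_start: int = 0,
) -> list[EvalRecord]:
    """Evaluate one configuration from several start frames.

    Each start gets a fresh backend set (tracker state must not leak
    between runs).  Default: five starts, 25 frames apart.
    """
    if ds.gt_masks is None:
        raise ValueError("multi_start_evaluate needs ground-truth masks")
    last = first_start + stride * (n_starts - 1)
    if last >= len(ds):
        raise ValueError(
            f"video of {len(ds)} frames too short for {n_starts} starts "
            f"{stride} apart (last start would be {last})"
        )
    records = []
    for j in range(n_starts):
        start = first_start + j * stride
        results, events = run(ds, make_backends(), cfg, start_frame=start)
        records.append(
            evaluate_run(results, ds.gt_masks, events,
                         strategy=cfg.strategy.label(), seed=cfg.seed)
        )
    return records


def pooled_iou(records: Iterable[EvalRecord]) -> np.ndarray:
    """Pool per-frame IoU across records (e.g. across start frames)."""
    return np.concatenate([r.per_frame_iou for r in records])


def sweep(
    ds: VideoDataset,
    make_backends: Callable[[], BackendSet],
    base_cfg: RunConfig,
    intervals: Sequence[int] = SWEEP_INTERVALS,
    alphas: Sequence[float] = SWEEP_ALPHAS,
    parameter_sets: Sequence[tuple[str, ...]] = SWEEP_PARAMETER_SETS,
    n_starts: int = 1,
    stride: int = 25,
) -> SweepResult:
    """Evaluate the full strategy grid on one video.

    The grid covers no re-prompting (R_inf), the interval ladder
    (default R_50..R_10 in steps of 10) plus per-frame re-prompting
    (R_1), and the scene-aware detector for every threshold factor alpha
    (default 2..10 in steps of 2) crossed with every monitored-parameter
    set.
    """
    strategies: list[Strategy] = [Strategy(kind="none")]
    strategies += [Strategy(kind="interval", n=n) for n in intervals]
    strategies += [Strategy(kind="interval", n=1)]
    for params in parameter_sets:
        for alpha in alphas:
            strategies.append(
                Strategy(kind="scene_aware", parameters=tuple(params),
                         alpha=float(alpha))
            )
    out = SweepResult()
    for strat in strategies:
        cfg = base_cfg.with_strategy(strat)
        out.records.extend(
            multi_start_evaluate(ds, make_backends, cfg,
                                 n_starts=n_starts, stride=stride)
        )
    return out


def compare_strategies(
    iou_a: Sequence[float], iou_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired IoUs.

    Zero differences are dropped (standard convention).  When every pair
    is identical the data carry no evidence either way: the result is
    flagged degenerate with p = 1.
    """
    a = np.asarray(iou_a, dtype=float)
    b = np.asarray(iou_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired sequences differ in length: {a.shape} vs {b.shape}")
    diffs = b - a
    if np.all(diffs == 0):
        return ComparisonResult(statistic=0.0, p_value=1.0, degenerate=True)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return ComparisonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def tradeoff_plot(table: pd.DataFrame, path) -> None:
    """Scatter the IoU-vs-FPS trade-off, one point per sweep cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(table["fps"], table["median_iou"], c="tab:blue")
    for _, row in table.iterrows():
        ax.annotate(str(row["strategy"]), (row["fps"], row["median_iou"]),
                    fontsize=6, alpha=0.7)
    ax.set_xlabel("simulated FPS")
    ax.set_ylabel("median IoU")
    ax.set_title("Segmentation accuracy vs. temporal resolution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
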