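"""Re-prompting policies: fixed-interval triggers and scene-aware CUSUM.

The scene-aware detector maintains, per monitored parameter, a tabular
CUSUM against a moving baseline: the target value mu_t is the moving
average of the five most recent observations (the current one included)
and sigma_t their sample standard deviation.  With deviation
dX_t = X_t - mu_t, the cumulative sums are

    S_t^+ = max(0, S_{t-1}^+ + dX_t - k*sigma_t)
    S_t^- = max(0, S_{t-1}^- - dX_t - k*sigma_t)

and a change is flagged when either sum exceeds the dynamic threshold
T = alpha * sigma_t.  The slack k (default 0.5) balances sensitivity
against prompting frequency; alpha sets the re-prompting sensitivity.

Interpretation choices (the baseline definition leaves several open;
see the methods note for the calibration argument): the window is the
W most recent observations including X_t — an exclusive window inflates
the variance of dX_t by (1 + 1/W) and, at W = 5, produces runaway
false-alarm rates; sigma_t uses ddof = 1, since the population estimate
on five samples biases sigma low and with it the threshold; and a
trigger fully resets the channel (sums and window), because
re-prompting re-initializes the pipeline and post-trigger statistics
should restart.  The first W observations are pure warm-up: no sums are
accumulated and no trigger can occur before observation W + 1.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .scene_monitor import SceneSample

__all__ = [
    "CusumChannel",
    "RepromptDecision",
    "cusum_update",
    "scene_aware_step",
    "interval_step",
    "replay_stream",
]

#: Relative floor on sigma_t: a constant window would give sigma_t = 0,
#: hence T = 0 and a trigger on float jitter; the floor preserves genuine
#: step detection while suppressing that degenerate case.
SIGMA_FLOOR_REL = 1e-6


@dataclass
class CusumChannel:
    """Running CUSUM state for one monitored scene parameter."""

    name: str
    window_w: int = 5
    k: float = 0.5
    alpha: float = 4.0
    window: deque = field(default_factory=deque)
    s_plus: float = 0.0
    s_minus: float = 0.0

    def reset(self) -> None:
        self.window.clear()
        self.s_plus = 0.0
        self.s_minus = 0.0


@dataclass(frozen=True)
class RepromptDecision:
    """Outcome of one policy step at one frame."""

    index: int
    triggered: bool
    reason: str = "none"  # cusum | interval | empty_mask | none
    trigger_channel: Optional[str] = None
    s_plus: float = 0.0
    s_minus: float = 0.0
    threshold_t: float = 0.0

    def __post_init__(self) -> None:
        if self.triggered and self.reason == "none":
            raise ValueError("a triggered decision needs a reason")


def cusum_update(ch: CusumChannel, x_t: float) -> tuple[bool, float, float, float]:
    """Advance one channel by one observation; returns (triggered, S+, S-, T).

    While the window is still warming up (fewer than W values) the
    observation is only recorded and no trigger can occur.  On a trigger
    the caller is expected to reset the channel.
    """
    if not math.isfinite(x_t):
        raise ValueError(f"non-finite observation {x_t!r} on channel {ch.name}")
    if len(ch.window) < ch.window_w:
        ch.window.append(float(x_t))
        return False, ch.s_plus, ch.s_minus, 0.0

    # Slide the window so it holds the W most recent values incl. x_t.
    ch.window.append(float(x_t))
    ch.window.popleft()
    win = np.fromiter(ch.window, dtype=float, count=len(ch.window))
    mu = float(win.mean())
    sigma = float(win.std(ddof=1))
    sigma_eff = max(sigma, SIGMA_FLOOR_REL * max(1.0, abs(mu)))
    dx = float(x_t) - mu
    ch.s_plus = max(0.0, ch.s_plus + dx - ch.k * sigma_eff)
    ch.s_minus = max(0.0, ch.s_minus - dx - ch.k * sigma_eff)
    threshold = ch.alpha * sigma_eff
    triggered = ch.s_plus > threshold or ch.s_minus > threshold
    return triggered, ch.s_plus, ch.s_minus, threshold


def scene_aware_step(
    channels: list[CusumChannel], sample: SceneSample
) -> RepromptDecision:
    """Update every channel with its parameter; OR-combine the triggers.

    A channel whose parameter is invalid this frame (e.g. consistency at
    the first frame) is skipped.  On any trigger all channels reset: the
    re-prompt restarts the monitored statistics.
    """
    if not channels:
        raise ValueError("scene-aware policy needs at least one channel")
    first: Optional[CusumChannel] = None
    stats = (0.0, 0.0, 0.0)
    for ch in channels:
        if not sample.valid(ch.name):
            continue
        trig, sp, sm, thr = cusum_update(ch, sample[ch.name])
        if trig and first is None:
            first = ch
            stats = (sp, sm, thr)
    if first is not None:
        for ch in channels:
            ch.reset()
        return RepromptDecision(
            index=sample.index, triggered=True, reason="cusum",
            trigger_channel=first.name,
            s_plus=stats[0], s_minus=stats[1], threshold_t=stats[2],
        )
    return RepromptDecision(index=sample.index, triggered=False)


def interval_step(
    n: Optional[int], frames_since_prompt: int, index: int = 0
) -> RepromptDecision:
    """Fixed-interval policy R_n; ``n=None`` encodes R_inf (never re-prompt)."""
    if n is not None and n < 1:
        raise ValueError(f"interval must be >= 1, got {n}")
    if frames_since_prompt < 0:
        raise ValueError("frames_since_prompt must be non-negative")
    triggered = n is not None and frames_since_prompt >= n
    return RepromptDecision(
        index=index, triggered=triggered,
        reason="interval" if triggered else "none",
    )


def replay_stream(
    values,
    *,
    window_w: int = 5,
    k: float = 0.5,
    alpha: float = 4.0,
    reset_on_trigger: bool = True,
    name: str = "x",
) -> pd.DataFrame:
    """Run the detector over a raw value stream for offline inspection.

    Returns one row per observation with (S+, S-, T, triggered).  With
    ``reset_on_trigger`` False the state keeps accumulating, which is
    useful for comparing trigger counts across alpha on one stream.
    """
    ch = CusumChannel(name=name, window_w=window_w, k=k, alpha=alpha)
    rows = []
    for i, x in enumerate(values):
        trig, sp, sm, thr = cusum_update(ch, float(x))
        rows.append(
            {"index": i, name: float(x), "s_plus": sp, "s_minus": sm,
             "threshold": thr, "triggered": trig}
        )
        if trig and reset_on_trigger:
            ch.reset()
    return pd.DataFrame(rows)
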