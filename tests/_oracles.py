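"""Independent brute-force oracles used to check the implementation.

These are deliberately written with explicit Python loops and from the
raw value stream, sharing no code with the package.
"""

from __future__ import annotations

import math


def cusum_oracle(
    stream,
    w: int = 5,
    k: float = 0.5,
    alpha: float = 4.0,
    reset_on_trigger: bool = True,
):
    """Recompute the detector trajectory step by step.

    Returns a list of (triggered, s_plus, s_minus, threshold) tuples, one
    per observation.  Baseline: the w most recent observations including
    the current one; sample standard deviation; first w observations are
    warm-up; a trigger (strictly above threshold) resets sums and history.
    """
    out = []
    hist: list[float] = []
    s_plus = s_minus = 0.0
    for x in stream:
        x = float(x)
        if len(hist) < w:
            hist.append(x)
            out.append((False, s_plus, s_minus, 0.0))
            continue
        hist.append(x)
        win = hist[-w:]
        mu = sum(win) / w
        var = sum((v - mu) ** 2 for v in win) / (w - 1)
        sigma = math.sqrt(var)
        sigma_eff = max(sigma, 1e-6 * max(1.0, abs(mu)))
        dx = x - mu
        s_plus = max(0.0, s_plus + dx - k * sigma_eff)
        s_minus = max(0.0, s_minus - dx - k * sigma_eff)
        threshold = alpha * sigma_eff
        triggered = s_plus > threshold or s_minus > threshold
        out.append((triggered, s_plus, s_minus, threshold))
        if triggered and reset_on_trigger:
            hist = []
            s_plus = s_minus = 0.0
    return out


def stride_prompt_oracle(points, s):
    """Prompt placement by explicit enumeration of the candidate list."""
    stride = max(1, math.ceil(s))
    chosen = []
    for i in range(len(points)):
        if i % stride == 0:
            chosen.append(tuple(points[i]))
    return chosen


def masked_depth_stats_oracle(depth, mask):
    """Mean / population std over masked valid-depth pixels, pixel by pixel."""
    vals = []
    h = len(depth)
    for y in range(h):
        for x in range(len(depth[0])):
            if mask[y][x] and depth[y][x] > 0:
                vals.append(depth[y][x])
    if not vals:
        return 0.0, 0.0, False
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return mean, math.sqrt(var), True
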