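"""Point-prompt generation from a per-pixel foreground probability map.

Pixels with foreground probability strictly above the candidate threshold
(default 0.9) become candidate prompt points.  The prompt spacing is

    s = sqrt(N) / f

with N the number of candidates and f a predefined spacing factor
(default 0.1).  Prompts are then taken as every ceil(s)-th candidate in
row-major scan order starting at the first, which yields about f*sqrt(N)
prompts spread through the candidate region (10 prompts for a full
100x100 region at f=0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CandidateSet",
    "PromptSet",
    "EmptyCandidateError",
    "select_candidates",
    "compute_spacing",
    "place_prompts",
    "prompts_from_probability",
]


class EmptyCandidateError(ValueError):
    """No pixel cleared the candidate threshold; the caller must handle this."""


@dataclass(frozen=True)
class CandidateSet:
    """Candidate prompt pixels in row-major scan order.

    ``points`` is an (N, 2) integer array of (x, y) pixel coordinates;
    ``N`` equals both the number of true pixels in ``mask`` and the
    number of rows.
    """

    mask: np.ndarray
    points: np.ndarray

    @property
    def N(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PromptSet:
    """Foreground point prompts for a promptable segmenter."""

    points: tuple[tuple[int, int], ...]
    spacing_s: float
    source_frame: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def to_jsonable(self) -> dict:
        return {
            "points": [list(p) for p in self.points],
            "spacing_s": self.spacing_s,
            "source_frame": self.source_frame,
        }


def select_candidates(prob: np.ndarray, threshold: float = 0.9) -> CandidateSet:
    """Candidate pixels: probability strictly greater than ``threshold``."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probability map has values outside [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    mask = prob > threshold
    ys, xs = np.nonzero(mask)  # np.nonzero scans row-major
    return CandidateSet(mask=mask, points=np.stack([xs, ys], axis=1))


def compute_spacing(N: int, f: float = 0.1) -> float:
    """Prompt spacing s = sqrt(N)/f."""
    if N < 1:
        raise EmptyCandidateError("cannot compute spacing for zero candidates")
    if f <= 0:
        raise ValueError(f"spacing factor must be positive, got {f}")
    return math.sqrt(N) / f


def place_prompts(cands: CandidateSet, s: float, source_frame: int = 0) -> PromptSet:
    """Every ceil(s)-th candidate in row-major order, starting at the first.

    Produces ceil(N / ceil(s)) >= 1 prompts, all of which satisfy the
    candidate predicate by construction.  Deterministic: no randomness.
    """
    if cands.N < 1:
        raise EmptyCandidateError("empty candidate set")
    stride = max(1, math.ceil(s))
    chosen = cands.points[::stride]
    points = tuple((int(x), int(y)) for x, y in chosen)
    return PromptSet(points=points, spacing_s=float(s),
                     source_frame=source_frame)


def prompts_from_probability(
    prob: np.ndarray,
    threshold: float = 0.9,
    f: float = 0.1,
    source_frame: int = 0,
) -> PromptSet:
    """Full chain: threshold -> spacing -> placement.

    Raises EmptyCandidateError when no pixel clears the threshold.
    """
    cands = select_candidates(prob, threshold)
    if cands.N == 0:
        raise EmptyCandidateError(
            f"no candidate pixels above {threshold} in frame {source_frame}"
        )
    s = compute_spacing(cands.N, f)
    return place_prompts(cands, s, source_frame=source_frame)
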