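"""Per-trial proportional gaze from raw fixation records.

Converts fixation durations on areas of interest (AOIs) into the fraction of
looking time each available option received between trial onset and choice,
plus the derived statistics used to characterize gaze biases (the correct-
minus-incorrect gaze difference and its per-participant quintile binning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FixationRecord",
    "GazeVector",
    "proportional_gaze",
    "gaze_difference",
    "quintile_bins",
]


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: trial index, AOI label (None = nonsymbol), duration, onset rank."""

    trial: int
    aoi: Optional[str]
    duration: float
    order: int

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError(f"fixation duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class GazeVector:
    """Proportional gaze on each available option, in option order.

    Proportions sum to 1, except when no available option was fixated at all,
    in which case every entry is exactly 0.
    """

    options: tuple
    proportions: np.ndarray

    def __getitem__(self, option_id):
        return float(self.proportions[self.options.index(option_id)])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


def proportional_gaze(fixations: Sequence[FixationRecord], available: Sequence[str]) -> GazeVector:
    """Share of total fixation time on each available option.

    Nonsymbol fixations (AOI ``None``) and fixations on options outside the
    available set are excluded from the denominator. If no available option
    was fixated, all proportions are 0 rather than undefined.
    """
    available = tuple(available)
    if not available:
        raise ValueError("available option set must not be empty")
    totals = {oid: 0.0 for oid in available}
    for fx in fixations:
        if fx.aoi in totals:
            totals[fx.aoi] += fx.duration
    denom = sum(totals.values())
    if denom <= 0:
        props = np.zeros(len(available))
    else:
        props = np.array([totals[oid] / denom for oid in available])
    return GazeVector(options=available, proportions=props)


def gaze_difference(gaze: GazeVector, correct) -> float:
    """Gaze share on the correct (higher-valued) option minus the incorrect one.

    Defined for two available options; ranges over [-1, 1], positive when the
    correct option had the relative gaze advantage, and 0 on no-fixation trials.
    """
    if len(gaze.options) != 2:
        raise ValueError("gaze_difference requires exactly two available options")
    if correct not in gaze.options:
        raise ValueError(f"correct option {correct!r} not among {gaze.options}")
    i = gaze.options.index(correct)
    return float(gaze.proportions[i] - gaze.proportions[1 - i])


def quintile_bins(scores: Sequence[float], n_bins: int = 5) -> np.ndarray:
    """Rank-based equal-size binning of one participant's scores.

    Scores are stably sorted (ties keep trial order) and split into
    ``n_bins`` contiguous groups. When the count is not divisible, the
    remainder goes to the lowest-index bins, so bin sizes differ by at most
    one and are non-increasing. Returns the 1-based bin index of each score
    in its original position.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} scores, got {n}")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if k < rem else base for k in range(n_bins)]
    bins = np.empty(n, dtype=int)
    start = 0
    for k, sz in enumerate(sizes, start=1):
        bins[order[start : start + sz]] = k
        start += sz
    return bins
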