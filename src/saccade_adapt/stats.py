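"""Behavioral summary statistics of adaptation series.

All statistics operate on per-trial displacement series (degrees) aligned
to a schedule: 4-trial binning, learning rates within a perturbation
window, percent (or absolute) loss across set breaks, the spontaneous
recovery index computed from three 8-trial windows, and the percent
contribution of each movement phase to total displacement.

Participants whose adaptation is too small for a ratio to be meaningful
(below 0.25 degrees by default) are excluded from the normalized
statistics rather than contributing unstable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedules import ExperimentSchedule

MIN_ADAPTATION_DEG = 0.25


@dataclass
class BinnedSeries:
    """Non-overlapping consecutive bin means; trailing partial bin dropped."""

    means: np.ndarray
    size: int
    starts: np.ndarray  # first trial index of each bin

    def __len__(self) -> int:
        return len(self.means)


def bin_series(series, size: int = 4) -> BinnedSeries:
    if size < 1:
        raise ValueError("bin size must be >= 1")
    x = np.asarray(series, dtype=float)
    n_bins = len(x) // size
    trimmed = x[: n_bins * size].reshape(n_bins, size)
    return BinnedSeries(
        means=trimmed.mean(axis=1),
        size=size,
        starts=np.arange(n_bins) * size,
    )


def learning_rate(series, window: tuple[int, int] | None = None,
                  bin_size: int = 4) -> float:
    """Mean increase in adaptation per trial over a window.

    Computed as (last bin mean - first bin mean) divided by the trial span
    between the two bins.  ``window`` is a half-open (start, stop) trial
    range; default is the whole series.
    """
    x = np.asarray(series, dtype=float)
    if window is not None:
        x = x[window[0]:window[1]]
    binned = bin_series(x, bin_size)
    if len(binned) < 2:
        raise ValueError("learning rate needs at least two full bins")
    span = binned.starts[-1] - binned.starts[0]
    return float((binned.means[-1] - binned.means[0]) / span)


@dataclass
class BreakDecayEntry:
    break_index: int
    pre: float
    post: float
    included: bool

    @property
    def percent_change(self) -> float | None:
        if not self.included:
            return None
        return 100.0 * (self.post - self.pre) / self.pre

    @property
    def absolute_change(self) -> float:
        return self.post - self.pre


@dataclass
class BreakDecayReport:
    entries: list[BreakDecayEntry]
    mode: str

    @property
    def mean_change(self) -> float | None:
        if self.mode == "percent":
            vals = [e.percent_change for e in self.entries if e.included]
        else:
            vals = [e.absolute_change for e in self.entries]
        if not vals:
            return None
        return float(np.mean(vals))


def set_break_decay(series, break_positions, min_adapt: float = MIN_ADAPTATION_DEG,
                    mode: str = "percent", bin_size: int = 4
                    ) -> BreakDecayReport:
    """Loss of adaptation across set breaks.

    For each break (index of the trial the break follows), compare the mean
    of the ``bin_size`` trials ending at the break against the mean of the
    ``bin_size`` trials after it.  Percent mode normalizes by the pre-break
    level and excludes breaks where adaptation had not reached ``min_adapt``
    degrees; absolute mode reports the raw change for every break.
    """
    if mode not in ("percent", "absolute"):
        raise ValueError("mode must be 'percent' or 'absolute'")
    x = np.asarray(series, dtype=float)
    entries = []
    for b in break_positions:
        if b - bin_size + 1 < 0 or b + bin_size >= len(x):
            continue  # break at series boundary: skipped
        pre = float(np.mean(x[b - bin_size + 1: b + 1]))
        post = float(np.mean(x[b + 1: b + 1 + bin_size]))
        included = mode == "absolute" or abs(pre) >= min_adapt
        entries.append(BreakDecayEntry(break_index=int(b), pre=pre, post=post,
                                       included=included))
    return BreakDecayReport(entries=entries, mode=mode)


@dataclass
class RecoveryWindows:
    """Three 8-trial windows: end of adaptation, end of extinction, and the
    start of the error-clamp block immediately after the final set break."""

    t1: tuple[int, int]
    t2: tuple[int, int]
    t3: tuple[int, int]
    length: int = 8

    def __post_init__(self) -> None:
        for w in (self.t1, self.t2, self.t3):
            if w[1] - w[0] != self.length:
                raise ValueError(f"window {w} must span {self.length} trials")
        if not (self.t1[1] <= self.t2[0] and self.t2[1] <= self.t3[0]):
            raise ValueError("windows must be ordered and non-overlapping")


def recovery_windows_for_exp2(schedule: ExperimentSchedule,
                              length: int = 8) -> RecoveryWindows:
    """Default window placement on an adaptation/extinction/clamp schedule."""
    phase = np.array([t.phase for t in schedule.trials], dtype=object)
    adapt = np.flatnonzero(phase == "perturbation")
    ext = np.flatnonzero(phase == "extinction")
    clamp = np.flatnonzero(phase == "clamp")
    if len(adapt) < length or len(ext) < length or len(clamp) < length:
        raise ValueError("schedule phases too short for recovery windows")
    return RecoveryWindows(
        t1=(int(adapt[-length]), int(adapt[-1]) + 1),
        t2=(int(ext[-length]), int(ext[-1]) + 1),
        t3=(int(clamp[0]), int(clamp[0]) + length),
        length=length,
    )


def spontaneous_recovery(series, windows: RecoveryWindows,
                         min_adapt: float = MIN_ADAPTATION_DEG
                         ) -> float | None:
    """Spontaneous recovery index [mean(t3) - mean(t2)] / mean(t1).

    Returns None (excluded) when adaptation at t1 is below ``min_adapt``.
    """
    x = np.asarray(series, dtype=float)
    m1 = float(np.mean(x[windows.t1[0]:windows.t1[1]]))
    m2 = float(np.mean(x[windows.t2[0]:windows.t2[1]]))
    m3 = float(np.mean(x[windows.t3[0]:windows.t3[1]]))
    if abs(m1) < min_adapt:
        return None
    return (m3 - m2) / m1


def phase_contribution(yA: float, yD: float) -> tuple[float, float] | None:
    """Percent contribution of the acceleration and deceleration periods."""
    total = yA + yD
    if total == 0.0:
        return None
    return (100.0 * yA / total, 100.0 * yD / total)
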