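"""Candidate-window enumeration and test-retest pair selection.

Two time series of the same pattern class are selected per recording and
compared pairwise. The default policy takes the chronologically first and
last qualifying windows (information-bias control); for the stationary
pattern the two windows with the highest stationarity (smallest baseline
drift) are taken instead. Selection never sees HRV values, so blinding to
the outcome holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import BpmTrace, ClassificationCriteria, PatternWindow, classify_window
from .preprocessing import QualityReport, RRSeries, quality_report

__all__ = ["CandidateWindow", "SegmentPair", "enumerate_windows", "select_pair"]


@dataclass
class CandidateWindow:
    """A sliding-window candidate with its quality and pattern evaluation."""

    start_s: float
    end_s: float
    quality: QualityReport
    pattern: PatternWindow | None = None

    @property
    def qualifies(self) -> bool:
        return self.quality.passes and self.pattern is not None


@dataclass
class SegmentPair:
    """The two windows compared for one recording/class/length."""

    class_label: str
    length_s: float
    first: PatternWindow
    second: PatternWindow
    policy: str


class SelectionError(ValueError):
    """Raised when a recording cannot supply two qualifying windows."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def enumerate_windows(
    series: RRSeries,
    length_s: float,
    step_s: float = 1.0,
    trace: BpmTrace | None = None,
    ga_weeks: float | None = None,
    criteria: ClassificationCriteria = ClassificationCriteria(),
    classify: bool = True,
) -> list[CandidateWindow]:
    """Slide windows of ``length_s`` at ``step_s`` over a corrected series.

    Each window carries a quality report computed over the beats inside it;
    when ``classify`` is true and a bpm trace is supplied (or derivable),
    each window is also pattern-classified.
    """
    t0, t1 = series.onset_time_s[0], series.onset_time_s[-1]
    if t1 - t0 < length_s:
        return []
    if classify and trace is None:
        from .patterns import to_bpm_trace

        trace = to_bpm_trace(series)
    ga = series.ga_weeks if ga_weeks is None else ga_weeks
    out: list[CandidateWindow] = []
    start = t0
    while start + length_s <= t1 + 1e-9:
        end = start + length_s
        sel = (series.onset_time_s >= start) & (series.onset_time_s <= end)
        q = quality_report(series.corrected_mask[sel])
        pattern = None
        if classify:
            win_end = min(end, trace.time_s[-1] + 1.0 / trace.sample_hz)
            pattern = classify_window(trace, (start, win_end), ga, criteria)
        out.append(CandidateWindow(start_s=start, end_s=end, quality=q, pattern=pattern))
        start += step_s
    return out


def _non_overlapping(a: CandidateWindow, b: CandidateWindow) -> bool:
    return a.end_s <= b.start_s or b.end_s <= a.start_s


def select_pair(
    candidates: list[CandidateWindow],
    class_label: str,
    policy: str = "first_last",
) -> SegmentPair:
    """Pick the analysed pair among qualifying candidates of one class.

    ``first_last`` takes the chronologically first and last qualifying
    windows; ``top_stationarity`` takes the two non-overlapping qualifying
    windows with the highest stationarity score (ties broken
    chronologically, earlier first), returned in time order.
    Raises :class:`SelectionError` when fewer than two non-overlapping
    qualifying windows exist.
    """
    if policy not in ("first_last", "top_stationarity"):
        raise ValueError(f"unknown policy {policy!r}")
    qual = [
        c for c in candidates
        if c.quality.passes and c.pattern is not None and class_label in c.pattern.labels
    ]
    qual.sort(key=lambda c: c.start_s)
    if len(qual) < 2:
        raise SelectionError(f"<2 qualifying windows for class {class_label}")

    if policy == "first_last":
        first = qual[0]
        last = next((c for c in reversed(qual) if _non_overlapping(first, c)), None)
        if last is None:
            raise SelectionError(f"no non-overlapping qualifying pair for {class_label}")
        chosen = (first, last)
    else:
        ranked = sorted(qual, key=lambda c: (-c.pattern.stationarity_score, c.start_s))
        best = ranked[0]
        partner = next((c for c in ranked[1:] if _non_overlapping(best, c)), None)
        if partner is None:
            raise SelectionError(f"no non-overlapping qualifying pair for {class_label}")
        chosen = tuple(sorted((best, partner), key=lambda c: c.start_s))

    a, b = chosen
    return SegmentPair(
        class_label=class_label,
        length_s=a.end_s - a.start_s,
        first=a.pattern,
        second=b.pattern,
        policy=policy,
    )
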