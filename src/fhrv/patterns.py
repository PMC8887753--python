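"""CTG-style heart-rate-pattern classification of fetal bpm traces.

RR intervals are converted to beats per minute, a floating baseline is
estimated, accelerations/decelerations (±15 bpm from baseline sustained
≥15 s) are detected, and candidate windows (64 s or 120 s) are labelled:

* SHRP — stationary heart rate pattern: no qualifying excursions and
  baseline drift < 10 bpm over the surrounding 2 minutes;
* HRP I (gestational age 24+1 to 32+0 weeks only): FHR < 160 bpm, drift
  < 10 bpm per 3 min, oscillation bandwidth < ±5 bpm, at most isolated
  accelerations;
* HRP II: oscillation bandwidth > ±5 bpm, FHR < 160 bpm outside qualifying
  accelerations;
* HRP III (GA 32+1 to 41+6 weeks only): bandwidth > ±10 bpm with frequent,
  long-lasting accelerations.

Labels are non-exclusive: a window may satisfy several classes and is
analysed once per class downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .preprocessing import RRSeries

__all__ = [
    "BpmTrace",
    "Excursion",
    "ClassificationCriteria",
    "PatternWindow",
    "to_bpm_trace",
    "estimate_baseline",
    "detect_excursions",
    "oscillation_bandwidth",
    "classify_window",
]


@dataclass
class BpmTrace:
    """Uniformly sampled fetal heart rate in bpm with an estimated baseline."""

    time_s: np.ndarray
    bpm: np.ndarray
    baseline_bpm: np.ndarray | None = None
    sample_hz: float = 4.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if np.any(self.bpm <= 0):
            raise ValueError("bpm must be positive")
        dt = np.diff(self.time_s)
        if dt.size and np.max(np.abs(dt - 1.0 / self.sample_hz)) > 1e-9:
            raise ValueError("bpm grid must be uniform at sample_hz")
        if self.baseline_bpm is not None:
            self.baseline_bpm = np.asarray(self.baseline_bpm, dtype=float)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class Excursion:
    """A contiguous deviation of ≥15 bpm from baseline."""

    start_s: float
    end_s: float
    peak_deviation_bpm: float
    kind: str  # "acceleration" | "deceleration"
    qualifies: bool

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ClassificationCriteria:
    """Numeric thresholds of the pattern definitions (all in printed units)."""

    excursion_amp_bpm: float = 15.0
    excursion_dur_s: float = 15.0
    shrp_drift_bpm: float = 10.0        # per 120 s
    shrp_drift_span_s: float = 120.0
    hrp1_drift_bpm: float = 10.0        # per 180 s
    hrp1_drift_span_s: float = 180.0
    bandwidth_low_bpm: float = 5.0
    bandwidth_high_bpm: float = 10.0
    tachy_bpm: float = 160.0
    hrp1_ga_range: tuple[float, float] = (24 + 1 / 7, 32.0)
    hrp3_ga_range: tuple[float, float] = (32 + 1 / 7, 41 + 6 / 7)
    # "isolated" vs "frequent" accelerations, per surrounding 10 minutes
    context_span_s: float = 600.0
    isolated_max_accels: int = 1
    frequent_min_accels: int = 2
    long_accel_dur_s: float = 30.0


@dataclass
class PatternWindow:
    """A candidate analysis window with its class labels and evaluation record."""

    start_s: float
    end_s: float
    labels: tuple[str, ...]
    evaluation: dict
    stationarity_score: float

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def to_bpm_trace(series: RRSeries, sample_hz: float = 4.0) -> BpmTrace:
    """Convert a corrected RR series to a 4 Hz bpm trace with baseline."""
    import warnings

    if series.duration_s < 120.0:
        warnings.warn("series shorter than 120 s; drift spans will be clipped",
                      stacklevel=2)
    t, rr = series.onset_time_s, series.rr_ms
    bpm_beats = 60000.0 / rr
    spline = CubicSpline(t, bpm_beats) if t.size >= 4 else CubicSpline(t, bpm_beats, bc_type="natural")
    n = int(np.floor((t[-1] - t[0]) * sample_hz)) + 1
    grid = t[0] + np.arange(n) / sample_hz
    trace = BpmTrace(time_s=grid, bpm=spline(grid), sample_hz=sample_hz)
    return estimate_baseline(trace)


def _rolling_median(x: np.ndarray, win: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )


def estimate_baseline(
    trace: BpmTrace,
    excursion_amp_bpm: float = 15.0,
    median_win_s: float = 60.0,
    smooth_win_s: float = 15.0,
) -> BpmTrace:
    """Two-pass floating-baseline estimate.

    Pass 1 is a centred 60-s running median (window shrinking at the edges);
    samples deviating ≥15 bpm from it — candidate accelerations and
    decelerations — are excluded and the median re-run on the remainder;
    the result is smoothed by a 15-s moving average. Defined at every grid
    point (excluded stretches are filled by interpolation).
    """
    if trace.duration_s < 64.0:
        raise ValueError("trace must span at least 64 s for baseline estimation")
    fs = trace.sample_hz
    mwin = max(3, int(round(median_win_s * fs)))
    pass1 = _rolling_median(trace.bpm, mwin)
    keep = np.abs(trace.bpm - pass1) < excursion_amp_bpm
    masked = pd.Series(np.where(keep, trace.bpm, np.nan))
    pass2 = masked.rolling(mwin, center=True, min_periods=max(3, mwin // 8)).median()
    pass2 = pass2.interpolate(limit_direction="both").to_numpy()
    swin = max(3, int(round(smooth_win_s * fs)))
    baseline = pd.Series(pass2).rolling(swin, center=True, min_periods=1).mean().to_numpy()
    return replace(trace, baseline_bpm=baseline)


def detect_excursions(
    trace: BpmTrace,
    amp_bpm: float = 15.0,
    dur_s: float = 15.0,
) -> list[Excursion]:
    """Maximal runs where |bpm − baseline| ≥ amp; qualifying iff ≥ dur_s long."""
    if trace.baseline_bpm is None:
        raise ValueError("baseline must be estimated first")
    dev = trace.bpm - trace.baseline_bpm
    above = np.abs(dev) >= amp_bpm
    out: list[Excursion] = []
    if not above.any():
        return out
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    dt = 1.0 / trace.sample_hz
    for i0, i1 in zip(starts, ends):
        seg = dev[i0:i1]
        peak = seg[np.argmax(np.abs(seg))]
        duration = (i1 - i0) * dt
        out.append(
            Excursion(
                start_s=float(trace.time_s[i0]),
                end_s=float(trace.time_s[i1 - 1] + dt),
                peak_deviation_bpm=float(peak),
                kind="acceleration" if peak > 0 else "deceleration",
                qualifies=duration >= dur_s,
            )
        )
    return out


def oscillation_bandwidth(
    trace: BpmTrace,
    window: tuple[float, float],
    excursions: list[Excursion] | None = None,
) -> float:
    """Half the 2.5–97.5 percentile span of (bpm − baseline) in the window.

    Samples inside qualifying excursions are excluded; percentiles rather
    than min/max keep single-sample noise from inflating the bandwidth.
    Returns NaN when the window is entirely covered by excursions.
    """
    if trace.baseline_bpm is None:
        raise ValueError("baseline must be estimated first")
    lo, hi = window
    sel = (trace.time_s >= lo) & (trace.time_s < hi)
    if excursions:
        for ex in excursions:
            if ex.qualifies:
                sel &= ~((trace.time_s >= ex.start_s) & (trace.time_s < ex.end_s))
    dev = (trace.bpm - trace.baseline_bpm)[sel]
    if dev.size == 0:
        return float("nan")
    p_lo, p_hi = np.percentile(dev, [2.5, 97.5])
    return float((p_hi - p_lo) / 2.0)


def _baseline_drift(trace: BpmTrace, center_s: float, span_s: float) -> float:
    """max − min of the estimated baseline over a centred, clipped span."""
    half = span_s / 2.0
    lo = max(trace.time_s[0], center_s - half)
    hi = min(trace.time_s[-1], center_s + half)
    sel = (trace.time_s >= lo) & (trace.time_s <= hi)
    b = trace.baseline_bpm[sel]
    return float(b.max() - b.min())


def classify_window(
    trace: BpmTrace,
    window: tuple[float, float],
    ga_weeks: float,
    criteria: ClassificationCriteria = ClassificationCriteria(),
) -> PatternWindow:
    """Label one candidate window with every pattern class it satisfies."""
    if trace.baseline_bpm is None:
        trace = estimate_baseline(trace, criteria.excursion_amp_bpm)
    lo, hi = window
    if lo < trace.time_s[0] - 1e-9 or hi > trace.time_s[-1] + 1.0 / trace.sample_hz + 1e-9:
        raise ValueError("window outside trace")
    center = (lo + hi) / 2.0
    excursions = detect_excursions(trace, criteria.excursion_amp_bpm, criteria.excursion_dur_s)
    qualifying = [e for e in excursions if e.qualifies]
    overlapping = [e for e in qualifying if e.start_s < hi and e.end_s > lo]

    in_win = (trace.time_s >= lo) & (trace.time_s < hi)
    mean_fhr = float(trace.bpm[in_win].mean())
    # FHR outside qualifying accelerations, for the tachycardia rules
    non_accel = in_win.copy()
    for e in qualifying:
        non_accel &= ~((trace.time_s >= e.start_s) & (trace.time_s < e.end_s))
    fhr_non_accel_max = float(trace.bpm[non_accel].max()) if non_accel.any() else float("nan")

    drift_shrp = _baseline_drift(trace, center, criteria.shrp_drift_span_s)
    drift_hrp1 = _baseline_drift(trace, center, criteria.hrp1_drift_span_s)
    bandwidth = oscillation_bandwidth(trace, window, qualifying)

    # surrounding-context acceleration counts (10-min span, clipped)
    ctx_lo = max(trace.time_s[0], center - criteria.context_span_s / 2.0)
    ctx_hi = min(trace.time_s[-1], center + criteria.context_span_s / 2.0)
    ctx_accels = [
        e for e in qualifying
        if e.kind == "acceleration" and e.start_s < ctx_hi and e.end_s > ctx_lo
    ]
    ctx_long_accels = [e for e in ctx_accels if e.duration_s >= criteria.long_accel_dur_s]

    labels: list[str] = []
    if not overlapping and drift_shrp < criteria.shrp_drift_bpm:
        labels.append("SHRP")
    ga_ok_1 = criteria.hrp1_ga_range[0] <= ga_weeks <= criteria.hrp1_ga_range[1]
    if (
        ga_ok_1
        and mean_fhr < criteria.tachy_bpm
        and drift_hrp1 < criteria.hrp1_drift_bpm
        and np.isfinite(bandwidth)
        and bandwidth < criteria.bandwidth_low_bpm
        and len(ctx_accels) <= criteria.isolated_max_accels
        and not any(e.kind == "acceleration" for e in overlapping)
    ):
        labels.append("HRP_I")
    if (
        np.isfinite(bandwidth)
        and bandwidth > criteria.bandwidth_low_bpm
        and (np.isnan(fhr_non_accel_max) or fhr_non_accel_max < criteria.tachy_bpm)
    ):
        labels.append("HRP_II")
    ga_ok_3 = criteria.hrp3_ga_range[0] <= ga_weeks <= criteria.hrp3_ga_range[1]
    if (
        ga_ok_3
        and np.isfinite(bandwidth)
        and bandwidth > criteria.bandwidth_high_bpm
        and len(ctx_long_accels) >= criteria.frequent_min_accels
    ):
        labels.append("HRP_III")

    evaluation = {
        "drift_bpm_per_span": drift_shrp,
        "drift_bpm_per_hrp1_span": drift_hrp1,
        "bandwidth_bpm": bandwidth,
        "n_qualifying_excursions": len(overlapping),
        "n_context_accels": len(ctx_accels),
        "mean_fhr_bpm": mean_fhr,
        "max_bpm": float(trace.bpm[in_win].max()),
    }
    return PatternWindow(
        start_s=lo,
        end_s=hi,
        labels=tuple(labels) if labels else ("unclassified",),
        evaluation=evaluation,
        stationarity_score=-drift_shrp,
    )
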