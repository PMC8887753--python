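"""Synthetic fetal RR recordings and paired measurements with known truth.

Fetal RR intervals sit around 360–510 ms (≈120–165 bpm). The generator
builds an instantaneous RR signal

    rr(t) = baseline(t) + accel(t) + a_LF sin(2π f_LF t + φ1)
                        + a_HF sin(2π f_HF t + φ2) + ε,   ε ~ N(0, σ²)

and emits beats iteratively, t_{k+1} = t_k + rr(t_k)/1000. LF/HF modulation
is additive in milliseconds so each sinusoid contributes an exactly known
band power a²/2 (ms²); accelerations are specified in bpm — the CTG
convention — and converted through rr = 60000/bpm. Every generator returns
a :class:`GroundTruth` so downstream stages can be tested without any
external recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import RRSeries

__all__ = [
    "SyntheticRecordingConfig",
    "ReliabilitySimConfig",
    "GroundTruth",
    "generate_rr_recording",
    "inject_artifacts",
    "generate_paired_measurements",
    "generate_pattern_trace",
]

_MIN_WINDOW_S = 64.0


@dataclass(frozen=True)
class SyntheticRecordingConfig:
    """Parameters of one synthetic fetal RR recording.

    Defaults emulate a quiet mid-gestation fetus: ~20 min recording, 430 ms
    baseline RR (≈140 bpm), mild baseline drift, sparse qualifying
    accelerations, LF/HF sinusoidal modulation inside the fetal bands
    (LF 0.04–0.4 Hz, HF 0.4–1.5 Hz), 3 ms beat noise and a 1% artifact rate.
    """

    duration_s: float = 1200.0
    base_rr_ms: float = 430.0
    drift_bpm_per_2min: float = 4.0
    accel_rate_per_min: float = 0.15
    accel_amplitude_bpm: float = 20.0
    accel_duration_s: float = 20.0
    lf_freq_hz: float = 0.1
    lf_amp_ms: float = 5.0
    hf_freq_hz: float = 0.8
    hf_amp_ms: float = 3.0
    noise_sd_ms: float = 3.0
    artifact_rate: float = 0.01
    ga_weeks: float = 30.0
    seed: int = 0
    fixed_phase: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.base_rr_ms <= 0:
            raise ValueError("duration_s and base_rr_ms must be positive")
        if not (0.04 <= self.lf_freq_hz < 0.4 <= self.hf_freq_hz <= 1.5):
            raise ValueError("LF/HF frequencies must lie in the fetal bands")
        if not (0.0 <= self.artifact_rate <= 0.2):
            raise ValueError("artifact_rate must be in [0, 0.2]")


@dataclass(frozen=True)
class ReliabilitySimConfig:
    """Paired log-normal measurement design with known variance components."""

    n_subjects: int = 48
    mu_log: float = 1.8
    sigma_b: float = 0.5
    sigma_e: float = 0.2
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("sigma_b and sigma_e must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    artifact_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_band_power_lf_ms2: float = 0.0
    true_band_power_hf_ms2: float = 0.0
    true_pattern_label: str | None = None
    true_sigma_b2: float | None = None
    true_sigma_e2: float | None = None


def _accel_profile(t: np.ndarray, starts: np.ndarray, amp_bpm: float, dur_s: float) -> np.ndarray:
    """Plateau excursion with smooth cosine ramps, summed over events.

    The plateau holds the full amplitude for all but the two short ramps, so
    an event of amplitude >= 15 bpm and duration >= 15 s genuinely sustains
    the qualifying deviation (peak-shaped profiles would not).
    """
    out = np.zeros_like(t)
    ramp = min(2.5, dur_s / 4.0)
    for s in starts:
        dt = t - s
        inside = (dt >= 0) & (dt <= dur_s)
        u = dt[inside]
        g = np.ones_like(u)
        g = np.where(u < ramp, np.sin(0.5 * np.pi * u / ramp) ** 2, g)
        tail = dur_s - u
        g = np.where(tail < ramp, np.sin(0.5 * np.pi * tail / ramp) ** 2, g)
        out[inside] += amp_bpm * g
    return out


def generate_rr_recording(config: SyntheticRecordingConfig) -> tuple[RRSeries, GroundTruth]:
    """Generate one beat-by-beat fetal RR recording.

    Beats are emitted iteratively at the instantaneous RR; the recording is
    clean (no artifacts) unless ``config.artifact_rate > 0``, in which case
    :func:`inject_artifacts` is applied afterwards with mixed kinds.
    """
    if config.duration_s < _MIN_WINDOW_S:
        raise ValueError(f"duration must cover at least one {_MIN_WINDOW_S:.0f}-s window")
    rng = np.random.default_rng(config.seed)
    phi1, phi2, phi3 = (
        (0.0, 0.0, 0.0) if config.fixed_phase else tuple(rng.uniform(0, 2 * np.pi, 3))
    )

    # bounded slow baseline wander: sinusoid whose steepest 120-s change
    # equals the configured drift rate (a linear ramp at that rate over a
    # full 20-min recording would sweep an unphysiological ~10x range)
    base_bpm = 60000.0 / config.base_rr_ms
    wander_period_s = 600.0
    wander_amp_bpm = (
        config.drift_bpm_per_2min * wander_period_s / (2 * np.pi * 120.0)
    )
    n_accels = rng.poisson(config.accel_rate_per_min * config.duration_s / 60.0)
    accel_starts = np.sort(rng.uniform(0, config.duration_s - config.accel_duration_s, n_accels)) \
        if n_accels and config.duration_s > config.accel_duration_s else np.array([])

    # generous upper bound on beat count
    max_beats = int(config.duration_s / (config.base_rr_ms / 1000.0) * 2) + 16
    times = np.empty(max_beats)
    rrs = np.empty(max_beats)
    t = 0.0
    k = 0
    while t < config.duration_s and k < max_beats:
        bpm = base_bpm + wander_amp_bpm * np.sin(2 * np.pi * t / wander_period_s + phi3)
        if accel_starts.size:
            bpm += _accel_profile(np.array([t]), accel_starts,
                                  config.accel_amplitude_bpm, config.accel_duration_s)[0]
        rr = 60000.0 / bpm
        rr += config.lf_amp_ms * np.sin(2 * np.pi * config.lf_freq_hz * t + phi1)
        rr += config.hf_amp_ms * np.sin(2 * np.pi * config.hf_freq_hz * t + phi2)
        if config.noise_sd_ms > 0:
            rr += rng.normal(0.0, config.noise_sd_ms)
        rr = max(rr, 150.0)  # physiological floor; guards pathological configs
        t += rr / 1000.0
        times[k] = t
        rrs[k] = rr
        k += 1
    # onset convention: onset[k] is the time of the beat ending interval k
    series = RRSeries(
        onset_time_s=np.cumsum(rrs[:k]) / 1000.0,
        rr_ms=rrs[:k].copy(),
        ga_weeks=config.ga_weeks,
        recording_id=f"synthetic-{config.seed}",
    )

    truth = GroundTruth(
        true_band_power_lf_ms2=config.lf_amp_ms**2 / 2.0,
        true_band_power_hf_ms2=config.hf_amp_ms**2 / 2.0,
        true_pattern_label=_intended_label(config, n_accels),
    )
    if config.artifact_rate > 0:
        series, art_truth = inject_artifacts(
            series, config.artifact_rate, seed=int(rng.integers(2**31))
        )
        truth.artifact_positions = art_truth.artifact_positions
    return series, truth


def _intended_label(config: SyntheticRecordingConfig, n_accels: int) -> str:
    if n_accels == 0 and config.drift_bpm_per_2min < 10:
        return "SHRP"
    return "not-SHRP"


def inject_artifacts(
    series: RRSeries,
    rate: float,
    kinds: frozenset[str] | set[str] = frozenset({"missed", "ectopic", "spike"}),
    seed: int = 0,
) -> tuple[RRSeries, GroundTruth]:
    """Corrupt a clean series with missed/ectopic/spike beat artifacts.

    missed: two adjacent intervals merged (≈2x RR, one beat removed);
    ectopic: one interval split into a short/long pair preserving total time;
    spike: one interval perturbed by ±(60–200) ms. Missed and ectopic
    preserve total recording duration. Ground truth lists the corrupted
    interval indices in the *output* series.
    """
    if not 0.0 <= rate <= 0.2:
        raise ValueError("artifact rate must be in [0, 0.2]")
    bad = set(kinds) - {"missed", "ectopic", "spike"}
    if bad:
        raise ValueError(f"unknown artifact kinds: {sorted(bad)}")
    n_corrupt = int(np.floor(rate * len(series)))
    if n_corrupt == 0:
        return series.copy(), GroundTruth()
    rng = np.random.default_rng(seed)
    kinds = sorted(kinds)
    rr = list(series.rr_ms)
    # even interior indices only: events never touch, so bookkeeping stays
    # exact (a missed-beat merge consumes the odd successor, never an event)
    candidates = np.arange(2, len(rr) - 2, 2)
    if n_corrupt > candidates.size:
        raise ValueError("series too short for requested artifact rate")
    positions = rng.choice(candidates, size=n_corrupt, replace=False)
    # apply from the end so earlier indices stay valid under insert/delete
    events = sorted(
        ((int(p), kinds[int(rng.integers(len(kinds)))]) for p in positions), reverse=True
    )
    shifts: list[tuple[int, int]] = []  # (original index, index delta for later positions)
    out_positions: list[int] = []
    for pos, kind in events:
        if kind == "missed":
            rr[pos] = rr[pos] + rr[pos + 1]
            del rr[pos + 1]
            shifts.append((pos, -1))
            out_positions.append(pos)
        elif kind == "ectopic":
            total = rr[pos]
            frac = rng.uniform(0.25, 0.45)
            rr[pos] = total * frac
            rr.insert(pos + 1, total * (1 - frac))
            shifts.append((pos, +1))
            out_positions.append(pos)  # one corrupted source interval, split in two
        else:  # spike
            delta = rng.uniform(60.0, 200.0) * rng.choice([-1.0, 1.0])
            if rr[pos] + delta <= 150.0:
                delta = abs(delta)
            rr[pos] = rr[pos] + delta
            out_positions.append(pos)
    # account for index shifts introduced by events applied later in time
    final_positions = []
    for p in out_positions:
        shift = sum(d for q, d in shifts if q < p)
        final_positions.append(p + shift)
    rr_arr = np.asarray(rr)
    onsets = series.onset_time_s[0] - series.rr_ms[0] / 1000.0 + np.cumsum(rr_arr) / 1000.0
    out = RRSeries(onsets, rr_arr, ga_weeks=series.ga_weeks,
                   recording_id=series.recording_id)
    return out, GroundTruth(artifact_positions=np.array(sorted(set(final_positions)), dtype=int))


def generate_paired_measurements(config: ReliabilitySimConfig) -> "pandas.DataFrame":
    """Log-normal replicate measurements with a random subject intercept.

    ``ln(value_ij) = mu_log + b_i + e_ij`` with ``b_i ~ N(0, sigma_b^2)``
    and ``e_ij ~ N(0, sigma_e^2)``. Returns a long-format DataFrame with
    columns ``subject``, ``replicate``, ``value`` (all values positive).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    b = rng.normal(0.0, config.sigma_b, config.n_subjects)
    e = rng.normal(0.0, config.sigma_e, (config.n_subjects, config.n_replicates))
    log_vals = config.mu_log + b[:, None] + e
    subjects = np.repeat(np.arange(config.n_subjects), config.n_replicates)
    replicates = np.tile(np.arange(config.n_replicates), config.n_subjects)
    return pd.DataFrame(
        {"subject": subjects, "replicate": replicates, "value": np.exp(log_vals).ravel()}
    )


def generate_pattern_trace(
    kind: str,
    *,
    duration_s: float = 300.0,
    base_bpm: float = 140.0,
    drift_bpm_per_2min: float = 12.0,
    accel_amplitude_bpm: float = 20.0,
    accel_duration_s: float = 20.0,
    oscillation_half_amp_bpm: float = 4.0,
    oscillation_freq_hz: float = 0.05,
    noise_sd_bpm: float = 0.5,
    sample_hz: float = 4.0,
    seed: int = 0,
):
    """A bpm trace of a known heart-rate-pattern kind, with its intended label.

    Kinds: ``flat`` (stationary, expected SHRP), ``drifting`` (baseline drift
    at ``drift_bpm_per_2min``, SHRP-disqualifying at >=10), ``accelerating``
    (one qualifying excursion, SHRP-disqualifying), ``oscillating``
    (sinusoidal oscillation whose half-amplitude straddles the ±5/±10 bpm
    cut-offs: < 5 bpm is intended HRP I, > 5 bpm intended HRP II).

    Returns ``(BpmTrace, intended_label)``; label is one of
    ``SHRP | not-SHRP | HRP_I | HRP_II``.
    """
    from .patterns import BpmTrace, estimate_baseline

    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * sample_hz)) / sample_hz
    bpm = np.full_like(t, base_bpm)
    if kind == "flat":
        label = "SHRP"
    elif kind == "drifting":
        bpm = bpm + drift_bpm_per_2min / 120.0 * t
        label = "not-SHRP" if drift_bpm_per_2min >= 10 else "SHRP"
    elif kind == "accelerating":
        start = duration_s / 2 - accel_duration_s / 2
        bpm = bpm + _accel_profile(t, np.array([start]), accel_amplitude_bpm, accel_duration_s)
        label = "not-SHRP"
    elif kind == "oscillating":
        bpm = bpm + oscillation_half_amp_bpm * np.sin(2 * np.pi * oscillation_freq_hz * t)
        label = "HRP_I" if oscillation_half_amp_bpm < 5.0 else "HRP_II"
    else:
        raise ValueError(f"unknown trace kind: {kind!r}")
    if noise_sd_bpm > 0:
        bpm = bpm + rng.normal(0.0, noise_sd_bpm, t.size)
    trace = BpmTrace(time_s=t, bpm=bpm, baseline_bpm=None)
    trace = estimate_baseline(trace)
    return trace, label
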