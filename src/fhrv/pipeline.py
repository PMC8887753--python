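"""End-to-end orchestration: simulate → preprocess → classify → select → HRV → reliability.

Interchange is plain text: RR recordings as CSV (``time_s,rr_ms,corrected``),
window annotations as BED-like TSV, per-segment parameters as long-format
CSV, and reliability tables as TSV. Every gate decision (quality failure,
missing class, exclusion) is recorded with a machine-readable reason, and
the whole run is reproducible from the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as pp
from . import synthetic
from .hrv import SpectralConfig, segment_measures
from .patterns import ClassificationCriteria, to_bpm_trace
from .preprocessing import DetrendConfig, RRSeries
from .reliability import AcceptabilityRule, reliability_report
from .selection import SelectionError, enumerate_windows, select_pair

logger = logging.getLogger("fhrv")

__all__ = ["PipelineConfig", "read_rr_csv", "write_rr_csv", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults are the study's printed values."""

    artifact_threshold_ms: float = 40.0
    threshold_overrides: dict[str, float] = field(default_factory=dict)  # per recording, e.g. 100
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    segment_lengths_s: tuple[float, ...] = (64.0, 120.0)
    step_s: float = 1.0
    policies: dict[str, str] = field(
        default_factory=lambda: {
            "SHRP": "top_stationarity",
            "HRP_I": "first_last",
            "HRP_II": "first_last",
            "HRP_III": "first_last",
        }
    )
    criteria: ClassificationCriteria = field(default_factory=ClassificationCriteria)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    acceptability: AcceptabilityRule = field(default_factory=AcceptabilityRule)
    detrend_time_domain: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detrend" in d and isinstance(d["detrend"], dict):
            d["detrend"] = DetrendConfig(**d["detrend"])
        if "criteria" in d and isinstance(d["criteria"], dict):
            c = dict(d["criteria"])
            for k in ("hrp1_ga_range", "hrp3_ga_range"):
                if k in c:
                    c[k] = tuple(c[k])
            d["criteria"] = ClassificationCriteria(**c)
        if "spectral" in d and isinstance(d["spectral"], dict):
            s = dict(d["spectral"])
            for k in ("lf_band", "hf_band"):
                if k in s:
                    s[k] = tuple(s[k])
            d["spectral"] = SpectralConfig(**s)
        if "acceptability" in d and isinstance(d["acceptability"], dict):
            d["acceptability"] = AcceptabilityRule(**d["acceptability"])
        if "segment_lengths_s" in d:
            d["segment_lengths_s"] = tuple(d["segment_lengths_s"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_rr_csv(path: str | Path) -> RRSeries:
    """Read an RR recording from CSV with header ``time_s,rr_ms[,corrected]``.

    Validates positivity and monotonicity (errors name the offending rows)
    and enforces onset/RR consistency; inconsistent onsets are rebuilt from
    the RR sequence with a warning.
    """
    import warnings

    df = pd.read_csv(path)
    for col in ("time_s", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rr = df["rr_ms"].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(rr <= 0)
    if bad.size:
        raise ValueError(f"{path}: nonpositive rr_ms at rows {[int(i) + 2 for i in bad]}")
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise ValueError(f"{path}: non-monotone time_s at rows {[int(i) + 2 for i in nonmono]}")
    if t.size > 1 and np.max(np.abs(np.diff(t) - rr[1:] / 1000.0)) > 1e-6:
        warnings.warn(f"{path}: onset times inconsistent with RR; rebuilding",
                      stacklevel=2)
        t = t[0] - rr[0] / 1000.0 + np.cumsum(rr) / 1000.0
    corrected = (
        df["corrected"].to_numpy(dtype=bool)
        if "corrected" in df.columns
        else np.zeros(rr.size, dtype=bool)
    )
    meta = {}
    return RRSeries(t, rr, corrected, recording_id=str(Path(path).stem), **meta)


def write_rr_csv(series: RRSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.onset_time_s,
            "rr_ms": series.rr_ms,
            "corrected": series.corrected_mask.astype(int),
        }
    ).to_csv(path, index=False)


def preprocess_recording(series: RRSeries, config: PipelineConfig) -> tuple[RRSeries, "pp.QualityReport"]:
    """Detect and correct artifacts; return corrected series + quality report."""
    thr = config.threshold_overrides.get(series.recording_id,
                                         config.artifact_threshold_ms)
    mask = pp.detect_artifacts(series, thr)
    corrected = pp.correct_artifacts(series, mask)
    return corrected, pp.quality_report(corrected)


def analyze_segment(series: RRSeries, start_s: float, end_s: float,
                    config: PipelineConfig) -> dict[str, float]:
    """Nine HRV parameters for one [start, end] window of a corrected series."""
    seg = series.slice_time(start_s, end_s)
    rr = seg.rr_ms
    rr_td = pp.detrend_smoothness_priors(rr, config.detrend.lambda_) \
        if config.detrend_time_domain else rr - 0.0
    tach = pp.resample_tachogram(seg, config.detrend.resample_hz)
    tach_d = pp.Tachogram(
        tach.time_s,
        pp.detrend_smoothness_priors(tach.rr_ms, config.detrend.lambda_),
        tach.sample_hz,
    )
    return segment_measures(rr_td, rr, tach_d, config.spectral).as_dict()


def run_pipeline(
    recordings: list[RRSeries] | None = None,
    *,
    n_synthetic: int = 0,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Run the full analysis over a cohort of recordings.

    ``recordings`` may be given directly, or ``n_synthetic`` seeded
    recordings are generated. Returns a dict with the per-segment long
    table, the grouped reliability tables and the exclusion log; when
    ``out_dir`` is given, all artifacts are also written as text files.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    if recordings is None:
        recordings = []
        for i in range(n_synthetic):
            cfg = synthetic.SyntheticRecordingConfig(
                seed=int(rng.integers(2**31)),
                ga_weeks=float(rng.uniform(20.0, 41.0)),
                base_rr_ms=float(rng.uniform(380.0, 500.0)),
                accel_rate_per_min=float(rng.choice([0.0, 0.0, 0.3])),
                drift_bpm_per_2min=float(rng.uniform(0.0, 6.0)),
                lf_amp_ms=float(rng.uniform(3.0, 8.0)),
                hf_amp_ms=float(rng.uniform(2.0, 6.0)),
            )
            rec, _ = synthetic.generate_rr_recording(cfg)
            rec.recording_id = f"sim{i:03d}"
            recordings.append(rec)

    seg_rows: list[dict] = []
    exclusions: list[dict] = []
    manifests: list[dict] = []
    window_rows: list[dict] = []
    corrected_store: list[RRSeries] = []
    for rec in recordings:
        try:
            corrected, quality = preprocess_recording(rec, config)
        except Exception as exc:  # structured stage error
            exclusions.append({"recording_id": rec.recording_id,
                               "stage": "preprocess", "reason": str(exc)})
            continue
        if not quality.passes:
            exclusions.append({
                "recording_id": rec.recording_id, "stage": "quality",
                "reason": f"fraction={quality.fraction_corrected:.3f},"
                          f"max_run={quality.max_consecutive_corrected}",
            })
            continue
        trace = to_bpm_trace(corrected)
        corrected_store.append(corrected)
        for length in config.segment_lengths_s:
            candidates = enumerate_windows(
                corrected, length, config.step_s, trace=trace,
                criteria=config.criteria,
            )
            if not candidates:
                exclusions.append({
                    "recording_id": rec.recording_id, "stage": "selection",
                    "reason": f"recording shorter than {length:.0f} s",
                })
                continue
            for c in candidates:
                if c.pattern is None:
                    continue
                ev = c.pattern.evaluation
                window_rows.append({
                    "recording_id": rec.recording_id,
                    "start_s": c.start_s, "end_s": c.end_s,
                    "label": ",".join(c.pattern.labels),
                    "stationarity_score": c.pattern.stationarity_score,
                    "drift_bpm": ev["drift_bpm_per_span"],
                    "bandwidth_bpm": ev["bandwidth_bpm"],
                    "n_accels": ev["n_context_accels"],
                    "quality_pass": c.quality.passes,
                })
            present = sorted({
                lab for c in candidates if c.quality.passes and c.pattern
                for lab in c.pattern.labels if lab != "unclassified"
            })
            for label in present:
                policy = config.policies.get(label, "first_last")
                try:
                    pair = select_pair(candidates, label, policy)
                except SelectionError as err:
                    exclusions.append({
                        "recording_id": rec.recording_id, "stage": "selection",
                        "reason": f"{label}/{length:.0f}s: {err.reason}",
                    })
                    continue
                manifests.append({
                    "recording_id": rec.recording_id, "class": label,
                    "length_s": length, "policy": policy,
                    "first_start_s": pair.first.start_s,
                    "second_start_s": pair.second.start_s,
                })
                for replicate, win in ((1, pair.first), (2, pair.second)):
                    try:
                        vals = analyze_segment(corrected, win.start_s, win.end_s, config)
                    except Exception as exc:
                        exclusions.append({
                            "recording_id": rec.recording_id, "stage": "hrv",
                            "reason": f"{label}/{length:.0f}s r{replicate}: {exc}",
                        })
                        continue
                    for param, value in vals.items():
                        seg_rows.append({
                            "recording_id": rec.recording_id,
                            "ga_weeks": rec.ga_weeks,
                            "class": label,
                            "length_s": length,
                            "replicate": replicate,
                            "parameter": param,
                            "value": value,
                        })
    segments = pd.DataFrame(seg_rows)
    if len(segments):
        positive = segments[segments["value"] > 0]
        main, per_n = reliability_report(positive, config.acceptability)
    else:
        main, per_n = pd.DataFrame(), pd.DataFrame()
    result = {
        "segments": segments,
        "reliability": main,
        "per_n": per_n,
        "manifests": pd.DataFrame(manifests),
        "exclusions": pd.DataFrame(exclusions),
        "windows": pd.DataFrame(window_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rr_dir = out / "corrected_rr"
        rr_dir.mkdir(exist_ok=True)
        for series in corrected_store:
            write_rr_csv(series, rr_dir / f"{series.recording_id}.csv")
        result["windows"].to_csv(out / "windows.tsv", sep="\t", index=False)
        segments.to_csv(out / "segments.csv", index=False)
        main.to_csv(out / "reliability.tsv", sep="\t", index=False)
        per_n.to_csv(out / "reliability_per_n.tsv", sep="\t", index=False)
        result["manifests"].to_csv(out / "segment_pairs.tsv", sep="\t", index=False)
        result["exclusions"].to_csv(out / "exclusions.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2,
                                                    default=str))
    return result
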