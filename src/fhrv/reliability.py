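"""Test–retest reliability statistics on the natural-log scale.

Each FHRV parameter is measured twice per fetus (two time series of the
same pattern class). On y = ln(value) the balanced two-replicate
random-intercept model

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_B^2),  e_ij ~ N(0, sigma_E^2)

has closed-form REML estimates: sigma_E^2 from within-pair differences,
sigma_B^2 from the variance of pair means (truncated at zero at the REML
boundary). From the components follow the within-subject coefficient of
variation CV = sqrt(exp(sigma_E^2) - 1), the intraclass correlation
ICC = sigma_B^2 / (sigma_B^2 + sigma_E^2), Bland–Altman 95% limits of
agreement back-transformed to a ratio scale, and the analytic
extrapolation to the average of n = 1..6 repeated time series
(sigma_E^2 -> sigma_E^2 / n). Acceptable reliability: CV <= 0.15 and
ICC >= 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementPairs",
    "ReliabilityResult",
    "AcceptabilityRule",
    "GA_GROUPS",
    "ga_group",
    "fit_variance_components",
    "within_cv",
    "icc",
    "bland_altman",
    "extrapolate_average_of_n",
    "reliability_report",
]

#: gestational-age groups in decimal weeks: closed intervals [lo, hi]
GA_GROUPS: dict[str, tuple[float, float]] = {
    "A": (20.0, 27 + 6 / 7),
    "B": (28.0, 34 + 6 / 7),
    "C": (35.0, 41.0),
}


def ga_group(ga_weeks: float) -> str | None:
    """Map decimal gestational weeks to group A/B/C (None outside)."""
    for name, (lo, hi) in GA_GROUPS.items():
        # group boundaries are week+day precise; half-day tolerance absorbs
        # float representation of e.g. 27+6/7
        if lo - 1e-9 <= ga_weeks <= hi + 0.5 / 7:
            return name
    return None


@dataclass(frozen=True)
class AcceptabilityRule:
    cv_max: float = 0.15
    icc_min: float = 0.80


@dataclass
class MeasurementPairs:
    """One parameter's paired positive measurements, one pair per subject."""

    subject: np.ndarray
    value_first: np.ndarray
    value_second: np.ndarray

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.value_first = np.asarray(self.value_first, dtype=float)
        self.value_second = np.asarray(self.value_second, dtype=float)
        if not (self.subject.size == self.value_first.size == self.value_second.size):
            raise ValueError("pair arrays must have equal length")
        for name, v in (("first", self.value_first), ("second", self.value_second)):
            if np.any(v <= 0) or np.any(~np.isfinite(v)):
                bad = self.subject[(v <= 0) | ~np.isfinite(v)]
                raise ValueError(
                    f"nonpositive/invalid {name} values for subjects {list(bad)}"
                )

    def __len__(self) -> int:
        return int(self.subject.size)


@dataclass
class ReliabilityResult:
    n_pairs: int
    mu_log: float
    sigma_b2: float
    sigma_e2: float
    cv_within: float
    cv_ci: tuple[float, float]
    icc: float
    loa_ratio: tuple[float, float]
    mean_log_diff: float
    median_value: float
    value_range: tuple[float, float]
    acceptable: bool
    per_n: pd.DataFrame = field(repr=False, default=None)


def fit_variance_components(pairs: MeasurementPairs) -> tuple[float, float, float]:
    """Closed-form REML variance components on the log scale.

    sigma_E^2 = sum(d_i^2) / (2m) with d_i the within-pair log difference;
    sigma_B^2 = max(0, var(pair means) - sigma_E^2 / 2) with the m-1
    denominator; mu = grand mean. Equals REML for the balanced
    two-replicate random-intercept model.
    """
    m = len(pairs)
    if m < 2:
        raise ValueError("need at least 2 pairs")
    y1 = np.log(pairs.value_first)
    y2 = np.log(pairs.value_second)
    d = y1 - y2
    means = (y1 + y2) / 2.0
    sigma_e2 = float(np.sum(d**2) / (2 * m))
    s2_means = float(np.var(means, ddof=1))
    sigma_b2 = max(0.0, s2_means - sigma_e2 / 2.0)
    mu = float(np.mean(means))
    return mu, sigma_b2, sigma_e2


def within_cv(sigma_e2: float) -> float:
    """Within-subject CV of a log-normal: sqrt(exp(sigma_E^2) - 1)."""
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be >= 0")
    return float(np.sqrt(np.expm1(sigma_e2)))


def _cv_ci(sigma_e2: float, m: int, level: float = 0.95) -> tuple[float, float]:
    """Chi-square interval on sigma_E^2 (m d.f.), mapped through the CV."""
    alpha = 1.0 - level
    lo = m * sigma_e2 / stats.chi2.ppf(1 - alpha / 2, m)
    hi = m * sigma_e2 / stats.chi2.ppf(alpha / 2, m)
    return within_cv(lo), within_cv(hi)


def icc(sigma_b2: float, sigma_e2: float) -> float:
    """Intraclass correlation sigma_B^2 / (sigma_B^2 + sigma_E^2)."""
    if sigma_b2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be >= 0")
    total = sigma_b2 + sigma_e2
    if total == 0:
        raise ValueError("ICC undefined when both variances are zero")
    return sigma_b2 / total


def bland_altman(pairs: MeasurementPairs):
    """Log-scale bias and 95% limits of agreement, plus ratio versions.

    d_i = ln(first) - ln(second); LoA_log = mean(d) ± 1.96 SD(d); the
    back-transformed exp(LoA) bounds the first/second ratio.
    Returns (mean_log_diff, (loa_log_lo, loa_log_hi), median_ratio,
    (ratio_lo, ratio_hi)).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    d = np.log(pairs.value_first) - np.log(pairs.value_second)
    mean_d = float(d.mean())
    # ddof=0 keeps the limits exactly consistent with the fitted sigma_E
    # (half-width 1.96*sqrt(2)*sigma_E) whenever the bias is zero
    sd_d = float(d.std(ddof=0))
    loa_log = (mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d)
    median_ratio = float(np.exp(np.median(d)))
    return mean_d, loa_log, median_ratio, (np.exp(loa_log[0]), np.exp(loa_log[1]))


def extrapolate_average_of_n(sigma_b2: float, sigma_e2: float, n: int):
    """Reliability when the mean of n repeated time series is the measurement.

    The within variance shrinks to sigma_E^2 / n; CV, ICC and the 95%
    prediction interval (ratio around the subject's true median) follow
    analytically. n = 1 reproduces the base statistics exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    se2_n = sigma_e2 / n
    cv_n = within_cv(se2_n)
    icc_n = icc(sigma_b2, se2_n)
    half = 1.96 * np.sqrt(se2_n)
    return cv_n, icc_n, (float(np.exp(-half)), float(np.exp(half)))


def analyze_pairs(
    pairs: MeasurementPairs,
    rule: AcceptabilityRule = AcceptabilityRule(),
    n_max: int = 6,
) -> ReliabilityResult:
    """Full reliability analysis of one parameter's pairs."""
    mu, sb2, se2 = fit_variance_components(pairs)
    cv = within_cv(se2)
    ci = _cv_ci(se2, len(pairs))
    icc_val = icc(sb2, se2)
    mean_d, _loa_log, _med_ratio, loa_ratio = bland_altman(pairs)
    values = np.concatenate([pairs.value_first, pairs.value_second])
    per_n = pd.DataFrame(
        [
            dict(zip(("n", "cv", "icc", "pi_lower", "pi_upper"),
                     (n, *_flatten(extrapolate_average_of_n(sb2, se2, n)))))
            for n in range(1, n_max + 1)
        ]
    )
    return ReliabilityResult(
        n_pairs=len(pairs),
        mu_log=mu,
        sigma_b2=sb2,
        sigma_e2=se2,
        cv_within=cv,
        cv_ci=ci,
        icc=icc_val,
        loa_ratio=loa_ratio,
        mean_log_diff=mean_d,
        median_value=float(np.median(values)),
        value_range=(float(values.min()), float(values.max())),
        acceptable=(cv <= rule.cv_max and icc_val >= rule.icc_min),
        per_n=per_n,
    )


def _flatten(res):
    cv_n, icc_n, (lo, hi) = res
    return cv_n, icc_n, lo, hi


def reliability_report(
    segments: pd.DataFrame,
    rule: AcceptabilityRule = AcceptabilityRule(),
    by_ga_group: bool = False,
    exclude_outliers: bool = False,
    outlier_factor: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped reliability tables from a long-format per-segment table.

    ``segments`` columns: ``recording_id, ga_weeks, class, length_s,
    replicate (1 or 2), parameter, value``. For every
    (parameter x class x length [x GA group]) cell with >= 3 complete
    pairs, the closed-form model is fitted and a row with n, median, range,
    CV (with chi-square CI), ratio LoA, ICC and the acceptability flag is
    emitted; smaller cells are reported as insufficient. Outliers (values
    above ``outlier_factor`` times the cell median) are retained by default;
    ``exclude_outliers`` drops their pairs as a sensitivity analysis.

    Returns ``(main_table, per_n_table)``.
    """
    required = {"recording_id", "ga_weeks", "class", "length_s", "replicate",
                "parameter", "value"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = segments.copy()
    df["ga_group"] = df["ga_weeks"].map(ga_group)
    keys = ["parameter", "class", "length_s"] + (["ga_group"] if by_ga_group else [])

    rows: list[dict] = []
    per_n_rows: list[pd.DataFrame] = []
    for key_vals, cell in df.groupby(keys, dropna=False):
        wide = cell.pivot_table(index="recording_id", columns="replicate",
                                values="value", aggfunc="first")
        wide = wide.dropna()
        label = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        if wide.shape[0] < 3 or not {1, 2}.issubset(wide.columns):
            rows.append({**label, "n": int(wide.shape[0]), "status": "insufficient"})
            continue
        if exclude_outliers:
            med = float(np.median(np.concatenate([wide[1], wide[2]])))
            keep = (wide[1] <= outlier_factor * med) & (wide[2] <= outlier_factor * med)
            wide = wide[keep]
            if wide.shape[0] < 3:
                rows.append({**label, "n": int(wide.shape[0]), "status": "insufficient"})
                continue
        pairs = MeasurementPairs(wide.index.to_numpy(), wide[1].to_numpy(),
                                 wide[2].to_numpy())
        res = analyze_pairs(pairs, rule)
        rows.append({
            **label,
            "n": res.n_pairs,
            "status": "ok",
            "median": res.median_value,
            "range_low": res.value_range[0],
            "range_high": res.value_range[1],
            "cv": res.cv_within,
            "cv_ci_low": res.cv_ci[0],
            "cv_ci_high": res.cv_ci[1],
            "loa_low": res.loa_ratio[0],
            "loa_high": res.loa_ratio[1],
            "icc": res.icc,
            "sigma_b2": res.sigma_b2,
            "sigma_e2": res.sigma_e2,
            "acceptable": res.acceptable,
        })
        pn = res.per_n.copy()
        for k, v in label.items():
            pn[k] = v
        per_n_rows.append(pn)
    main = pd.DataFrame(rows)
    per_n = pd.concat(per_n_rows, ignore_index=True) if per_n_rows else pd.DataFrame()
    return main, per_n
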