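"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(brute-force loops, numeric likelihood maximization) so agreement is a
genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def brute_force_time_domain(rr: list[float]) -> tuple[float, float, float]:
    """Mean/SDNN/RMSSD via explicit loops (no numpy reductions)."""
    n = len(rr)
    mean = sum(rr) / n
    ss = 0.0
    for v in rr:
        ss += (v - mean) ** 2
    sdnn = math.sqrt(ss / (n - 1))
    sq = 0.0
    for a, b in zip(rr[:-1], rr[1:]):
        sq += (b - a) ** 2
    rmssd = math.sqrt(sq / (n - 1))
    return mean, sdnn, rmssd


def reml_oracle(y1: np.ndarray, y2: np.ndarray) -> tuple[float, float]:
    """Iterative REML for the balanced two-replicate random-intercept model.

    Maximizes the restricted likelihood numerically by brent search on the
    profiled variance ratio rho = (sigma_b^2 + sigma_e^2/2) / sigma_e^2,
    with sigma_e^2 profiled out in closed form at each rho. Returns
    (sigma_b2, sigma_e2).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    m = y1.size
    d = y1 - y2
    means = (y1 + y2) / 2.0
    ssd = float(np.sum(d**2))
    ssm = float(np.sum((means - means.mean()) ** 2))

    def se2_profile(rho: float) -> float:
        # minimizer of the criterion in sigma_e^2 at fixed rho
        return (ssd / 2.0 + ssm / rho) / (2 * m - 1)

    def dprofile(log_rho: float) -> float:
        # envelope-theorem derivative of the profiled -2 log REML in log rho
        rho = math.exp(log_rho)
        sm = rho * se2_profile(rho)
        return (m - 1) - ssm / sm

    lo, hi = math.log(0.5), math.log(1e12)
    if dprofile(lo) >= 0.0:
        # criterion increasing on the whole feasible range → boundary
        rho = 0.5
        se2 = se2_profile(rho)
        return 0.0, se2
    root = brentq(dprofile, lo, hi, xtol=1e-15, rtol=8.9e-16)
    rho = math.exp(root)
    se2 = se2_profile(rho)
    return max(0.0, se2 * (rho - 0.5)), se2


def sine_percentile_halfspan(amplitude: float) -> float:
    """2.5–97.5 percentile half-span of a densely sampled sinusoid."""
    th = np.linspace(0, 2 * np.pi, 200001)
    x = amplitude * np.sin(th)
    lo, hi = np.percentile(x, [2.5, 97.5])
    return (hi - lo) / 2.0
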