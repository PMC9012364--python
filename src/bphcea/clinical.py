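"""Clinical mapping layer: symptom scores to severity states, trajectory
lookup on the cycle grid, adverse-event rate extrapolation, and the
catheterization burden of surgical strategies.

The International Prostate Symptom Score (IPSS, 0-35) is modelled per cycle
as a normal distribution with the trajectory's mean and SD; the cohort
fraction in each severity band (mild / moderate / severe) is the normal mass
between the configured cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .deck import CostTable, IPSSTrajectory, StrategySpec, UtilityCatalog, IPSS_MAX

__all__ = [
    "SeverityDistribution",
    "severity_from_ipss",
    "trajectory_at",
    "extrapolate_ae_rates",
    "rate_at",
    "expected_catheter_burden",
]


@dataclass(frozen=True)
class SeverityDistribution:
    p_mild: float
    p_moderate: float
    p_severe: float

    def as_dict(self) -> dict[str, float]:
        return {"mild": self.p_mild, "moderate": self.p_moderate, "severe": self.p_severe}

    def expected(self, by_severity: dict[str, float]) -> float:
        """Severity-weighted average of a per-severity quantity."""
        return (self.p_mild * by_severity["mild"]
                + self.p_moderate * by_severity["moderate"]
                + self.p_severe * by_severity["severe"])


def severity_from_ipss(mean: float, sd: float,
                       cutoffs: tuple[float, float] = (7.5, 19.5),
                       truncate: bool = False) -> SeverityDistribution:
    """Partition a normal IPSS distribution into severity-band masses.

    Parameters
    ----------
    mean, sd
        Moments of the cohort's IPSS distribution at one time point.
    cutoffs
        (mild_max, moderate_max) band edges applied to the continuous score.
    truncate
        If true, renormalize the normal to the score's support [0, 35]
        before partitioning.

    With ``sd == 0`` the distribution is a point mass at ``mean``.
    """
    if sd < 0:
        raise ValueError("IPSS standard deviation must be >= 0")
    lo, hi = cutoffs
    if not lo < hi:
        raise ValueError("severity cutoffs must be increasing")
    if sd == 0:
        if mean <= lo:
            return SeverityDistribution(1.0, 0.0, 0.0)
        if mean <= hi:
            return SeverityDistribution(0.0, 1.0, 0.0)
        return SeverityDistribution(0.0, 0.0, 1.0)
    inv = 1.0 / (sd * math.sqrt(2.0))

    def cdf(x: float) -> float:
        return 0.5 * (1.0 + math.erf((x - mean) * inv))

    if truncate:
        z0, z1 = cdf(0.0), cdf(IPSS_MAX)
        mass = z1 - z0
        p_mild = (cdf(lo) - z0) / mass
        p_mod = (cdf(hi) - cdf(lo)) / mass
    else:
        p_mild = cdf(lo)
        p_mod = cdf(hi) - cdf(lo)
    p_sev = 1.0 - p_mild - p_mod if not truncate else 1.0 - p_mild - p_mod
    # guard tiny negative round-off
    p_sev = max(p_sev, 0.0)
    tot = p_mild + p_mod + p_sev
    return SeverityDistribution(p_mild / tot, p_mod / tot, p_sev / tot)


def trajectory_at(traj: IPSSTrajectory, t: float,
                  rule: str = "carry_forward",
                  horizon: float | None = None) -> tuple[float, float]:
    """IPSS (mean, sd) at time ``t`` years post-treatment.

    Grid points are returned exactly.  Off-grid times use either the last
    preceding grid value (``carry_forward``, the default step-function rule)
    or linear interpolation (``linear``).  Times beyond the last grid point
    carry the final value forward under either rule.
    """
    times = np.asarray(traj.times, dtype=float)
    means = np.asarray(traj.means, dtype=float)
    sds = np.asarray(traj.sds, dtype=float)
    hi = horizon if horizon is not None else times[-1]
    if t < -1e-12 or t > max(hi, times[-1]) + 1e-12:
        raise ValueError(f"time {t} outside [0, {hi}]")
    exact = np.where(np.abs(times - t) < 1e-9)[0]
    if exact.size:
        i = exact[0]
        return float(means[i]), float(sds[i])
    if rule == "linear":
        return (float(np.interp(t, times, means)), float(np.interp(t, times, sds)))
    i = int(np.searchsorted(times, t, side="right")) - 1
    i = max(i, 0)
    return float(means[i]), float(sds[i])


def extrapolate_ae_rates(observed: list[tuple[float, float]],
                         extension_times: list[float]) -> list[tuple[float, float]]:
    """Extend an observed adverse-event rate schedule to later cycles.

    The extension continues the last observed per-cycle change: each later
    cycle's rate drops by the difference between the last two observed rates,
    floored at zero (after which it stays zero).  When the last observed
    change is non-decreasing — or only one point was observed — the last
    rate is held constant.
    """
    if not observed:
        raise ValueError("at least one observed rate is required")
    obs = sorted(observed)
    for t, r in obs:
        if r < 0:
            raise ValueError(f"negative observed rate {r} at t={t}")
    last_t, last_r = obs[-1]
    delta = obs[-1][1] - obs[-2][1] if len(obs) >= 2 else 0.0
    out = list(obs)
    r = last_r
    for t in extension_times:
        if t <= last_t + 1e-12:
            continue
        if delta < 0:
            r = max(r + delta, 0.0)
        out.append((t, r))
    return out


def rate_at(schedule, t: float) -> float:
    """Per-cycle rate applying to the cycle starting at ``t`` (0 if absent)."""
    for ts, r in schedule:
        if abs(ts - t) < 1e-9:
            return float(r)
    return 0.0


def expected_catheter_burden(strategy: StrategySpec,
                             utilities: UtilityCatalog,
                             costs: CostTable,
                             days_per_year: float = 365.25) -> tuple[float, float]:
    """Per-patient QALY decrement and cost of post-procedure catheterization.

    The decrement covers the catheter-wear disutility over the mean indwelling
    duration; the cost covers the extra catheter-removal office visit required
    by a fraction of catheterized patients.
    """
    if not strategy.is_surgical:
        raise ValueError("catheter burden applies to surgical strategies only")
    rate = strategy.catheterization_rate
    qaly_dec = rate * (strategy.catheter_duration_days / days_per_year) \
        * utilities.disutility_catheter
    cost = rate * strategy.extra_removal_visit_fraction * costs.office_visit
    return qaly_dec, cost
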