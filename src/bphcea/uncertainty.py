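"""Sensitivity and scenario machinery.

* one-way sensitivity (OWSA): each registered parameter varied to 0.9x and
  1.1x of base, model rerun, top-10 tornado entries by outcome spread;
* probabilistic sensitivity (PSA): every registered parameter drawn uniformly
  within [base - SD, base + SD] (parameters without a published SD use
  +/-10% of base), the cohort model rerun per draw;
* scenario analysis: swap in an alternative trajectory table and rerun;
* calibration of the model's open parameters (retreatment mixes, post-year-1
  retreatment scale, severity-cutoff shift) against published totals.

All stochastic operations take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .deck import InputDeck, RetreatmentPolicy, SEVERITIES
from .economics import CEAResult, StrategyTotals, incremental_analysis
from .engine import run_cohort

log = logging.getLogger(__name__)

__all__ = [
    "ParameterSpec",
    "UncertaintySettings",
    "TornadoEntry",
    "PSAPoint",
    "PSAResult",
    "build_default_registry",
    "get_param",
    "set_param",
    "run_owsa",
    "run_psa",
    "run_scenario",
    "CalibrationParameter",
    "default_open_parameters",
    "calibrate_open_parameters",
]


# ---------------------------------------------------------------------------
# parameter registry: dotted paths into the deck
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """One registered uncertain parameter.

    ``path`` is a dotted path into the deck, e.g.
    ``strategies[WVTT].procedure_cost`` or
    ``utilities.utility_by_severity[severe]``.  Two pseudo-leaves are
    supported: ``retreatment.rate_scale`` (multiplies the whole retreatment
    schedule; base 1.0) and ``trajectories[X].means[i]`` (one trajectory grid
    point).  ``sd`` is the published standard deviation where available;
    parameters without one are varied by the fractional ``rel_width`` of base.
    ``lo``/``hi`` clamp sampled values to the field's valid range.
    """

    name: str
    path: str
    sd: float | None = None
    lo: float = -math.inf
    hi: float = math.inf


def _tokens(path: str):
    for tok in path.split("."):
        if "[" in tok:
            attr, _, rest = tok.partition("[")
            yield attr, rest[:-1]
        else:
            yield tok, None


def _walk(deck: InputDeck, path: str):
    """Return (parent_container, final_attr, final_key) for a path."""
    obj = deck
    toks = list(_tokens(path))
    for attr, key in toks[:-1]:
        if attr == "strategies":
            obj = obj.strategy(key)
        elif attr == "trajectories":
            obj = obj.trajectories[key]
        else:
            obj = getattr(obj, attr)
            if key is not None:
                obj = obj[key]
    return obj, toks[-1]


def get_param(deck: InputDeck, path: str) -> float:
    obj, (attr, key) = _walk(deck, path)
    if attr == "rate_scale":
        return 1.0
    val = getattr(obj, attr) if not isinstance(obj, dict) else obj[attr]
    if key is not None:
        val = val[int(key)] if isinstance(val, (tuple, list)) else val[key]
    return float(val)


def set_param(deck: InputDeck, path: str, value: float) -> None:
    obj, (attr, key) = _walk(deck, path)
    if attr == "rate_scale":
        # multiplicative scale on a retreatment schedule
        sched = tuple((t, min(max(r * value, 0.0), 1.0))
                      for t, r in obj.rate_schedule)
        obj.rate_schedule = sched
        return
    if key is None:
        setattr(obj, attr, value)
        return
    cur = getattr(obj, attr)
    if isinstance(cur, dict):
        cur[key] = value
    elif isinstance(cur, tuple):
        lst = list(cur)
        lst[int(key)] = value
        setattr(obj, attr, tuple(lst))
    else:
        cur[int(key)] = value


def build_default_registry(deck: InputDeck,
                           include_trajectories: bool = True) -> list[ParameterSpec]:
    """Registry covering treatment costs, utilities, follow-up costs, rates,
    discounting, and (optionally) every trajectory grid point with its
    published SD."""
    reg: list[ParameterSpec] = []
    for st in deck.strategies:
        if st.is_surgical:
            reg.append(ParameterSpec(f"{st.name} Treatment Cost",
                                     f"strategies[{st.name}].procedure_cost", lo=0.0))
            if st.catheterization_rate > 0:
                reg.append(ParameterSpec(f"{st.name} Catheterization Rate",
                                         f"strategies[{st.name}].catheterization_rate",
                                         lo=0.0, hi=1.0))
        elif st.drug_cost_per_day > 0:
            reg.append(ParameterSpec(f"{st.name} Treatment Cost",
                                     f"strategies[{st.name}].drug_cost_per_day", lo=0.0))
        if st.retreatment.rate_schedule:
            reg.append(ParameterSpec(f"{st.name} Retreatment Rate",
                                     f"strategies[{st.name}].retreatment.rate_scale",
                                     lo=0.0))
    for sev in SEVERITIES:
        reg.append(ParameterSpec(f"{sev.capitalize()} BPH Utility",
                                 f"utilities.utility_by_severity[{sev}]",
                                 lo=0.0, hi=1.0))
        reg.append(ParameterSpec(f"{sev.capitalize()} BPH Follow-up Cost",
                                 f"costs.followup_by_severity[{sev}]", lo=0.0))
    reg.append(ParameterSpec("Office Visit Cost", "costs.office_visit", lo=0.0))
    reg.append(ParameterSpec("Medical Therapy Annual Cost",
                             "costs.medical_therapy_annual", lo=0.0))
    reg.append(ParameterSpec("Discount Rate", "settings.discount_rate_annual", lo=0.0))
    reg.append(ParameterSpec("Catheter Disutility",
                             "utilities.disutility_catheter", lo=0.0, hi=1.0))
    if include_trajectories:
        for name, tr in sorted(deck.trajectories.items()):
            for i, (t, m, sd) in enumerate(zip(tr.times, tr.means, tr.sds)):
                if t == 0:
                    continue  # shared baseline, not a treatment effect
                reg.append(ParameterSpec(f"{name} IPSS at {t:g}y",
                                         f"trajectories[{name}].means[{i}]",
                                         sd=sd, lo=0.0, hi=35.0))
    return reg


# ---------------------------------------------------------------------------
# settings / results containers
# ---------------------------------------------------------------------------

@dataclass
class UncertaintySettings:
    owsa_fraction: float = 0.10
    psa_draws: int = 1000
    rng_seed: int = 0
    rel_width: float = 0.10      # PSA interval half-width when no SD is known
    registry: list[ParameterSpec] = field(default_factory=list)
    metric: str = "icer"         # OWSA outcome: "icer" or "nmb"


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


@dataclass
class PSAPoint:
    draw: int
    costs: dict[str, float]
    qalys: dict[str, float]


@dataclass
class PSAResult:
    reference: str
    points: list[PSAPoint]
    base: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            for s in p.costs:
                rows.append({"draw": p.draw, "strategy": s,
                             "cost": p.costs[s], "qaly": p.qalys[s]})
        return pd.DataFrame(rows)

    def quadrant_fractions(self) -> dict[str, dict[str, float]]:
        """Per strategy: fraction of draws cheaper / more effective than the
        reference."""
        out: dict[str, dict[str, float]] = {}
        n = len(self.points)
        names = [s for s in self.points[0].costs if s != self.reference]
        for s in names:
            cheaper = sum(p.costs[s] < p.costs[self.reference] for p in self.points)
            better = sum(p.qalys[s] > p.qalys[self.reference] for p in self.points)
            out[s] = {"cheaper": cheaper / n, "more_effective": better / n}
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _totals(deck: InputDeck, names=None) -> list[StrategyTotals]:
    names = names or deck.strategy_names()
    out = []
    for n in names:
        tr = run_cohort(deck, n)
        out.append(StrategyTotals(n, tr.total_cost, tr.total_qalys, tr.life_years))
    return out


def _pair_outcome(deck: InputDeck, strategy: str, reference: str, metric: str) -> float:
    ts = run_cohort(deck, strategy)
    tr = run_cohort(deck, reference)
    dc = ts.total_cost - tr.total_cost
    dq = ts.total_qalys - tr.total_qalys
    if metric == "nmb":
        return dq * deck.settings.wtp_threshold - dc
    if abs(dq) < 1e-12:
        return math.copysign(math.inf, dc) if dc else 0.0
    return dc / dq


def run_owsa(deck: InputDeck, comparison: tuple[str, str],
             settings: UncertaintySettings | None = None,
             top: int = 10) -> list[TornadoEntry]:
    """One-way sensitivity: tornado of the ``top`` most influential parameters.

    Each registered parameter is moved to (1 - f) and (1 + f) of its base
    value in turn (f = ``owsa_fraction``), the two-strategy comparison is
    rerun, and entries are ranked by spread (ties broken alphabetically).
    Perturbations that would leave a field's valid range are clamped, with a
    logged warning.
    """
    settings = settings or UncertaintySettings()
    registry = settings.registry or build_default_registry(deck,
                                                           include_trajectories=False)
    strategy, reference = comparison
    entries = []
    for spec in registry:
        base = get_param(deck, spec.path)
        outcomes = []
        for mult in (1.0 - settings.owsa_fraction, 1.0 + settings.owsa_fraction):
            val = base * mult
            if val < spec.lo or val > spec.hi:
                clamped = min(max(val, spec.lo), spec.hi)
                log.warning("OWSA: %s perturbed to %g, clamped to %g",
                            spec.name, val, clamped)
                val = clamped
            d = deck.copy()
            set_param(d, spec.path, val)
            outcomes.append(_pair_outcome(d, strategy, reference, settings.metric))
        entries.append(TornadoEntry(spec.name, outcomes[0], outcomes[1]))
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries[:top]


def run_psa(deck: InputDeck, settings: UncertaintySettings | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every registered parameter is sampled uniformly on
    [base - SD, base + SD] (or base*(1 +/- rel_width) without an SD); values
    outside the field's valid range are resampled (up to 100 attempts) then
    clamped.  The cohort model is rerun deterministically per draw.
    """
    settings = settings or UncertaintySettings()
    registry = settings.registry or build_default_registry(deck)
    rng = np.random.default_rng(settings.rng_seed)
    names = deck.strategy_names()
    reference = deck.settings.reference_strategy
    base = {t.name: (t.cost, t.qalys) for t in _totals(deck)}

    specs = [(s, get_param(deck, s.path)) for s in registry]
    points = []
    for draw in range(settings.psa_draws):
        d = deck.copy()
        for spec, b in specs:
            half = spec.sd if spec.sd is not None else abs(b) * settings.rel_width
            lo, hi = b - half, b + half
            val = b
            if half > 0:
                for _ in range(100):
                    val = rng.uniform(lo, hi)
                    if spec.lo <= val <= spec.hi:
                        break
                else:
                    val = min(max(val, spec.lo), spec.hi)
                val = min(max(val, spec.lo), spec.hi)
            set_param(d, spec.path, val)
        costs, qalys = {}, {}
        for n in names:
            tr = run_cohort(d, n)
            costs[n], qalys[n] = tr.total_cost, tr.total_qalys
        points.append(PSAPoint(draw, costs, qalys))
    return PSAResult(reference=reference, points=points, base=base)


def run_scenario(deck: InputDeck, scenario: pd.DataFrame) -> CEAResult:
    """Rerun the full analysis with an alternative trajectory table.

    ``scenario`` must match the ``ipss_trajectories.csv`` schema
    (strategy, time_years, ipss_mean, ipss_sd); strategies absent from the
    table keep their base trajectories.
    """
    required = {"strategy", "time_years", "ipss_mean", "ipss_sd"}
    missing = required - set(scenario.columns)
    if missing:
        raise ValueError(f"scenario table missing columns {sorted(missing)}")
    d = deck.copy()
    from .deck import IPSSTrajectory

    for name, grp in scenario.groupby("strategy"):
        grp = grp.sort_values("time_years")
        d.trajectories[str(name)] = IPSSTrajectory(
            strategy=str(name),
            times=tuple(float(t) for t in grp["time_years"]),
            means=tuple(float(m) for m in grp["ipss_mean"]),
            sds=tuple(float(s) for s in grp["ipss_sd"]),
        )
    return incremental_analysis(_totals(d), d.settings.reference_strategy,
                                d.settings.wtp_threshold)


# ---------------------------------------------------------------------------
# calibration of open parameters
# ---------------------------------------------------------------------------

@dataclass
class CalibrationParameter:
    """One free parameter of the calibration search.

    ``apply(deck, value)`` mutates a deck copy; ``bounds`` constrain the
    search; ``x0`` is the starting point (the documented default).
    """

    name: str
    bounds: tuple[float, float]
    x0: float
    apply: callable = None  # type: ignore[assignment]


def _apply_ct_mist_mix(deck: InputDeck, v: float) -> None:
    """v = share of drug-therapy failures sent to the costlier MIST (PUL)."""
    for st in deck.strategies:
        if not st.is_surgical:
            st.retreatment.mix = {"WVTT": 1.0 - v, "PUL": v}


def _make_repeat_share(name: str):
    """v = share of this procedure's failures repeating the same procedure
    (the rest receive symptom-managing medical therapy)."""
    def apply(deck: InputDeck, v: float) -> None:
        st = deck.strategy(name)
        st.retreatment.mix = {"medical_therapy": 1.0 - v, "repeat_same": v}
    return apply


def _apply_post_year1_scale(deck: InputDeck, g: float) -> None:
    for st in deck.strategies:
        st.retreatment.rate_schedule = tuple(
            (t, min(max(r * g, 0.0), 1.0)) if t >= 1.0 - 1e-9 else (t, r)
            for t, r in st.retreatment.rate_schedule)


def _apply_cutoff_shift(deck: InputDeck, d: float) -> None:
    deck.settings.severity_cutoff_mild = 7.5 + d
    deck.settings.severity_cutoff_moderate = 19.5 + d


def default_open_parameters(deck: InputDeck | None = None
                            ) -> list[CalibrationParameter]:
    """The documented open parameters: the drug-failure MIST split, one
    repeat-same share per procedure, the post-year-1 retreatment scale, and
    the severity-cutoff shift."""
    params = [
        CalibrationParameter("ct_mist_pul_share", (0.0, 1.0), 0.0,
                             _apply_ct_mist_mix),
        CalibrationParameter("post_year1_retreat_scale", (0.0, 3.0), 1.0,
                             _apply_post_year1_scale),
        CalibrationParameter("severity_cutoff_shift", (-1.0, 0.5), 0.0,
                             _apply_cutoff_shift),
    ]
    surgical = ([s.name for s in deck.strategies if s.is_surgical]
                if deck is not None else ["PUL", "WVTT", "PVP", "TURP"])
    for name in surgical:
        params.append(CalibrationParameter(f"repeat_share_{name}", (0.0, 1.0),
                                           0.0, _make_repeat_share(name)))
    return params


def _apply_vector(deck: InputDeck, params: list[CalibrationParameter],
                  x: np.ndarray) -> InputDeck:
    d = deck.copy()
    for p, v in zip(params, x):
        p.apply(d, float(v))
    return d


def calibrate_open_parameters(deck: InputDeck,
                              targets: dict[str, tuple[float, float]],
                              free: list[CalibrationParameter] | None = None,
                              maxiter: int = 400):
    """Fit the open parameters to published per-strategy (cost, QALY) totals.

    Minimizes the sum of squared relative deviations with a deterministic
    multi-start Nelder-Mead search (the documented defaults plus three
    interior points of the bounds box; out-of-bounds trial points are
    penalized and the final answer clipped).  Returns
    ``(fitted_deck, fitted_values, residuals)`` where ``residuals`` maps each
    strategy to its relative (cost, QALY) deviation at the optimum.  An empty
    ``free`` list returns the deck unchanged with the defaults' residuals.
    """
    def residuals_of(d: InputDeck) -> dict[str, tuple[float, float]]:
        out = {}
        for name, (tc, tq) in targets.items():
            tr = run_cohort(d, name)
            out[name] = ((tr.total_cost - tc) / tc, (tr.total_qalys - tq) / tq)
        return out

    def sse(res: dict[str, tuple[float, float]]) -> float:
        return sum(rc * rc + rq * rq for rc, rq in res.values())

    if not free:
        res = residuals_of(deck)
        return deck, {}, res

    lo = np.array([p.bounds[0] for p in free])
    hi = np.array([p.bounds[1] for p in free])
    x0 = np.array([p.x0 for p in free])

    def objective(x):
        xc = np.clip(x, lo, hi)
        d = _apply_vector(deck, free, xc)
        penalty = float(np.sum((x - xc) ** 2))
        return sse(residuals_of(d)) + 1e3 * penalty

    starts = [x0] + [lo + frac * (hi - lo) for frac in (0.25, 0.5, 0.75)]
    best = None
    for start in starts:
        result = optimize.minimize(objective, start, method="Nelder-Mead",
                                   options={"maxiter": maxiter, "xatol": 1e-4,
                                            "fatol": 1e-10, "adaptive": True})
        if best is None or result.fun < best.fun:
            best = result
    xbest = np.clip(best.x, lo, hi)
    fitted = _apply_vector(deck, free, xbest)
    values = {p.name: float(v) for p, v in zip(free, xbest)}
    return fitted, values, residuals_of(fitted)
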