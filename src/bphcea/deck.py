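"""Input-deck data model for the BPH treatment cost-utility model.

An :class:`InputDeck` is the complete parameterization of one model run: the
economic settings (horizon, cycle plan, discounting, willingness-to-pay), the
cohort definition, one :class:`StrategySpec` per treatment strategy with its
adverse-event profiles and retreatment policy, the symptom-score trajectories,
the cost and utility catalogs, and a male life table.

Validation is total: :func:`validate_deck` returns a list of
:class:`Violation` records (empty iff the deck is valid) and never raises on
well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AE_CATEGORIES",
    "SEVERITIES",
    "RETREAT_MEDICAL",
    "RETREAT_REPEAT",
    "INVASIVENESS_RANK",
    "EconSettings",
    "CohortSpec",
    "AEProfile",
    "RetreatmentPolicy",
    "FollowupSchedule",
    "StrategySpec",
    "IPSSTrajectory",
    "CostTable",
    "UtilityCatalog",
    "LifeTable",
    "InputDeck",
    "Violation",
    "validate_deck",
]

AE_CATEGORIES = ("periprocedural", "short_term", "long_term")
SEVERITIES = ("mild", "moderate", "severe")

# Retreatment mix option keys (besides concrete strategy names).
RETREAT_MEDICAL = "medical_therapy"
RETREAT_REPEAT = "repeat_same"

# Invasiveness ranking used to validate retreatment mixes: a failed index
# treatment may not be followed by a *less* invasive procedure.  Medical
# therapy is always allowed after a procedure (symptom management), and drug
# therapy failures go to a minimally invasive surgical treatment.
INVASIVENESS_RANK = {"CT": 0, "PUL": 1, "WVTT": 1, "PVP": 2, "TURP": 3}

IPSS_MAX = 35.0


@dataclass
class EconSettings:
    """Economic and numerical settings for one model run.

    ``cycle_plan`` is the ordered list of cycle lengths in years; the default
    is four quarterly cycles followed by four annual cycles (5-year horizon).
    Discounting is applied at each cycle's start time, compounded continuously
    in t: factor (1+r)^(-t).  ``half_cycle_correction`` moves the discount
    point to the cycle midpoint instead.
    """

    discount_rate_annual: float = 0.03
    wtp_threshold: float = 50_000.0
    horizon_years: float = 5.0
    cycle_plan: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25, 1.0, 1.0, 1.0, 1.0)
    reference_strategy: str = "CT"
    half_cycle_correction: bool = False
    # IPSS severity cutoffs between mild/moderate and moderate/severe, applied
    # to the continuous normal model (continuity-corrected AUA bands).
    severity_cutoff_mild: float = 7.5
    severity_cutoff_moderate: float = 19.5
    truncate_ipss: bool = False
    trajectory_rule: str = "carry_forward"  # or "linear"
    days_per_year: float = 365.25

    def cycle_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.cycle_plan)[:-1]])


@dataclass
class CohortSpec:
    start_age: float = 63.0
    baseline_ipss_mean: float = 22.0
    baseline_ipss_sd: float = 4.8
    cohort_size: float = 1.0


@dataclass
class AEProfile:
    """One adverse event attached to a strategy.

    ``rate_schedule`` holds (time_years, per-cycle probability) pairs, with
    times on the cycle-start grid.  Periprocedural events may only carry a
    nonzero rate at the index cycle (t = 0).  ``annual_cost`` is the ongoing
    yearly management cost charged while a long-term event is active;
    ``unit_cost`` is the one-off treatment cost charged at incidence.
    ``recovery_time`` (years) bounds how long the disutility (and, for
    long-term events, the annual cost) persists.
    """

    name: str
    category: str
    rate_schedule: tuple[tuple[float, float], ...] = ()
    unit_cost: float = 0.0
    annual_cost: float = 0.0
    disutility: float = 0.0
    recovery_time: float = 0.25


@dataclass
class RetreatmentPolicy:
    """Per-cycle retreatment probabilities and the destination mix.

    ``rate_schedule``: (time_years, per-cycle probability) on the cycle-start
    grid, applied to the not-yet-retreated pool.  ``mix`` maps destination
    options (strategy names, ``medical_therapy`` or ``repeat_same``) to
    probabilities summing to 1.
    """

    rate_schedule: tuple[tuple[float, float], ...] = ()
    mix: dict[str, float] = field(default_factory=dict)


@dataclass
class FollowupSchedule:
    """Office-visit schedule.

    ``first_year_visits``: visits charged in the index cycle (two for every
    strategy: drug initiation + 1-month check, or two post-procedure checks).
    Severity-dependent annual follow-up (including post-void residual testing)
    is charged from year 2 onward through the cost table's per-severity annual
    amounts.
    """

    first_year_visits: float = 2.0
    annual_visits_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 1.0, "moderate": 1.0, "severe": 2.0}
    )
    pvr_tests_per_year: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.0, "moderate": 1.0, "severe": 1.0}
    )


@dataclass
class StrategySpec:
    name: str
    is_surgical: bool = True
    procedure_cost: float = 0.0
    drug_cost_per_day: float = 0.0
    catheterization_rate: float = 0.0
    catheter_duration_days: float = 0.0
    extra_removal_visit_fraction: float = 0.5
    ae_profiles: tuple[AEProfile, ...] = ()
    retreatment: RetreatmentPolicy = field(default_factory=RetreatmentPolicy)
    followup: FollowupSchedule = field(default_factory=FollowupSchedule)


@dataclass
class IPSSTrajectory:
    """Post-treatment IPSS mean/SD on a coarse time grid (absolute scores)."""

    strategy: str
    times: tuple[float, ...] = ()
    means: tuple[float, ...] = ()
    sds: tuple[float, ...] = ()


@dataclass
class CostTable:
    office_visit: float = 87.0
    followup_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 87.0, "moderate": 97.0, "severe": 184.0}
    )
    medical_therapy_annual: float = 105.0
    ae_costs: dict[str, float] = field(default_factory=dict)
    retreatment_costs: dict[str, float] = field(default_factory=dict)


@dataclass
class UtilityCatalog:
    utility_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.95, "moderate": 0.90, "severe": 0.80}
    )
    disutility_catheter: float = 0.20
    disutility_by_ae: dict[str, float] = field(default_factory=dict)
    recovery_time_by_ae: dict[str, float] = field(default_factory=dict)
    disutility_retreatment: float = 0.05
    retreatment_disutility_duration: float = 0.25


@dataclass
class LifeTable:
    """Age-indexed annual death probabilities (male)."""

    ages: tuple[float, ...] = ()
    qx: tuple[float, ...] = ()

    def annual_q(self, age: float) -> float:
        """Annual death probability at the integer age attained."""
        a = math.floor(age + 1e-9)
        ages = np.asarray(self.ages)
        idx = np.where(ages == a)[0]
        if idx.size == 0:
            raise ValueError(f"age {a} not covered by life table "
                             f"(range {ages.min()}-{ages.max()})")
        return float(np.asarray(self.qx)[idx[0]])


@dataclass
class InputDeck:
    settings: EconSettings = field(default_factory=EconSettings)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    strategies: tuple[StrategySpec, ...] = ()
    trajectories: dict[str, IPSSTrajectory] = field(default_factory=dict)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityCatalog = field(default_factory=UtilityCatalog)
    life_table: LifeTable = field(default_factory=LifeTable)
    provenance: dict[str, str] = field(default_factory=dict)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"strategy {name!r} not in deck")

    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def copy(self) -> "InputDeck":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass(frozen=True)
class Violation:
    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field} = {self.value!r} violates: {self.rule}"


def _frac(v, name, out):
    if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
        out.append(Violation(name, v, "must be a fraction in [0, 1]"))


def _nonneg(v, name, out):
    if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0.0):
        out.append(Violation(name, v, "must be finite and >= 0"))


def validate_deck(deck: InputDeck) -> list[Violation]:
    """Check every type invariant; returns violations as data, never raises."""
    v: list[Violation] = []
    s = deck.settings

    _nonneg(s.discount_rate_annual, "settings.discount_rate_annual", v)
    if not s.wtp_threshold > 0:
        v.append(Violation("settings.wtp_threshold", s.wtp_threshold, "must be > 0"))
    if abs(sum(s.cycle_plan) - s.horizon_years) > 1e-9:
        v.append(Violation("settings.cycle_plan", s.cycle_plan,
                           f"cycle lengths must sum to horizon ({s.horizon_years})"))
    if any(c <= 0 for c in s.cycle_plan):
        v.append(Violation("settings.cycle_plan", s.cycle_plan, "cycle lengths must be > 0"))
    if not s.severity_cutoff_mild < s.severity_cutoff_moderate:
        v.append(Violation("settings.severity_cutoff_mild",
                           (s.severity_cutoff_mild, s.severity_cutoff_moderate),
                           "severity cutoffs must be increasing"))
    if s.trajectory_rule not in ("carry_forward", "linear"):
        v.append(Violation("settings.trajectory_rule", s.trajectory_rule,
                           "must be 'carry_forward' or 'linear'"))
    if deck.strategies and s.reference_strategy not in deck.strategy_names():
        v.append(Violation("settings.reference_strategy", s.reference_strategy,
                           "must name a strategy in the deck"))

    c = deck.cohort
    if not (0.0 <= c.baseline_ipss_mean <= IPSS_MAX):
        v.append(Violation("cohort.baseline_ipss_mean", c.baseline_ipss_mean,
                           "must lie in [0, 35]"))
    if not c.baseline_ipss_sd > 0:
        v.append(Violation("cohort.baseline_ipss_sd", c.baseline_ipss_sd, "must be > 0"))

    seen = set()
    for st in deck.strategies:
        pre = f"strategies[{st.name}]"
        if st.name in seen:
            v.append(Violation(pre + ".name", st.name, "duplicate strategy name"))
        seen.add(st.name)
        _nonneg(st.procedure_cost, pre + ".procedure_cost", v)
        _nonneg(st.drug_cost_per_day, pre + ".drug_cost_per_day", v)
        _frac(st.catheterization_rate, pre + ".catheterization_rate", v)
        _frac(st.extra_removal_visit_fraction, pre + ".extra_removal_visit_fraction", v)
        _nonneg(st.catheter_duration_days, pre + ".catheter_duration_days", v)
        if not st.is_surgical:
            if st.procedure_cost != 0:
                v.append(Violation(pre + ".procedure_cost", st.procedure_cost,
                                   "non-surgical strategy must have procedure_cost = 0"))
            if st.catheterization_rate != 0:
                v.append(Violation(pre + ".catheterization_rate", st.catheterization_rate,
                                   "non-surgical strategy must have catheterization_rate = 0"))
        for ae in st.ae_profiles:
            aepre = f"{pre}.ae[{ae.name}]"
            if ae.category not in AE_CATEGORIES:
                v.append(Violation(aepre + ".category", ae.category,
                                   f"must be one of {AE_CATEGORIES}"))
            for t, r in ae.rate_schedule:
                _frac(r, f"{aepre}.rate@t={t}", v)
                if ae.category == "periprocedural" and t > 0 and r > 0:
                    v.append(Violation(f"{aepre}.rate@t={t}", r,
                                       "periprocedural rates must be zero after the index cycle"))
            _nonneg(ae.unit_cost, aepre + ".unit_cost", v)
            _nonneg(ae.annual_cost, aepre + ".annual_cost", v)
            _frac(ae.disutility, aepre + ".disutility", v)
            _nonneg(ae.recovery_time, aepre + ".recovery_time", v)

        rp = st.retreatment
        for t, r in rp.rate_schedule:
            _frac(r, f"{pre}.retreatment.rate@t={t}", v)
        if rp.mix:
            tot = sum(rp.mix.values())
            if abs(tot - 1.0) > 1e-9:
                v.append(Violation(pre + ".retreatment.mix", tot, "mix must sum to 1"))
            for opt, p in rp.mix.items():
                _frac(p, f"{pre}.retreatment.mix[{opt}]", v)
                if opt in (RETREAT_MEDICAL, RETREAT_REPEAT):
                    if opt == RETREAT_MEDICAL and not st.is_surgical and p > 0:
                        v.append(Violation(f"{pre}.retreatment.mix[{opt}]", p,
                                           "drug-therapy failures must move to a procedure"))
                    continue
                rank_idx = INVASIVENESS_RANK.get(st.name)
                rank_opt = INVASIVENESS_RANK.get(opt)
                if rank_idx is not None and rank_opt is not None and p > 0:
                    if not st.is_surgical and rank_opt > 1:
                        v.append(Violation(f"{pre}.retreatment.mix[{opt}]", p,
                                           "drug-therapy failures are retreated with a "
                                           "minimally invasive procedure"))
                    elif st.is_surgical and rank_opt < rank_idx:
                        v.append(Violation(f"{pre}.retreatment.mix[{opt}]", p,
                                           "retreatment may not be less invasive than the "
                                           "index procedure"))

        if st.name not in deck.trajectories:
            v.append(Violation(f"trajectories[{st.name}]", None,
                               "every strategy requires an IPSS trajectory"))

    for name, tr in deck.trajectories.items():
        pre = f"trajectories[{name}]"
        if len(tr.times) != len(tr.means) or len(tr.times) != len(tr.sds):
            v.append(Violation(pre, (len(tr.times), len(tr.means), len(tr.sds)),
                               "times/means/sds must have equal length"))
            continue
        if len(tr.times) == 0:
            v.append(Violation(pre, (), "trajectory must have at least one point"))
            continue
        if list(tr.times) != sorted(tr.times):
            v.append(Violation(pre + ".times", tr.times, "times must be increasing"))
        for i, (m, sd) in enumerate(zip(tr.means, tr.sds)):
            if not (0.0 <= m <= IPSS_MAX):
                v.append(Violation(f"{pre}.means[{i}]", m, "IPSS mean must lie in [0, 35]"))
            if not sd > 0:
                v.append(Violation(f"{pre}.sds[{i}]", sd, "IPSS SD must be > 0"))
        if tr.times and abs(tr.times[0]) < 1e-9:
            if (abs(tr.means[0] - deck.cohort.baseline_ipss_mean) > 1e-9
                    or abs(tr.sds[0] - deck.cohort.baseline_ipss_sd) > 1e-9):
                v.append(Violation(pre + "@t=0", (tr.means[0], tr.sds[0]),
                                   "time-0 point must equal the cohort baseline"))

    ct = deck.costs
    _nonneg(ct.office_visit, "costs.office_visit", v)
    _nonneg(ct.medical_therapy_annual, "costs.medical_therapy_annual", v)
    for sev in SEVERITIES:
        if sev not in ct.followup_by_severity:
            v.append(Violation(f"costs.followup_by_severity[{sev}]", None, "missing severity"))
        else:
            _nonneg(ct.followup_by_severity[sev], f"costs.followup_by_severity[{sev}]", v)
    for k, val in ct.ae_costs.items():
        _nonneg(val, f"costs.ae_costs[{k}]", v)
    for k, val in ct.retreatment_costs.items():
        _nonneg(val, f"costs.retreatment_costs[{k}]", v)

    ut = deck.utilities
    for sev in SEVERITIES:
        if sev not in ut.utility_by_severity:
            v.append(Violation(f"utilities.utility_by_severity[{sev}]", None, "missing severity"))
        else:
            _frac(ut.utility_by_severity[sev], f"utilities.utility_by_severity[{sev}]", v)
    u = ut.utility_by_severity
    if all(s in u for s in SEVERITIES):
        if not (u["mild"] >= u["moderate"] >= u["severe"]):
            v.append(Violation("utilities.utility_by_severity", dict(u),
                               "utilities must be ordered mild >= moderate >= severe"))
    _frac(ut.disutility_catheter, "utilities.disutility_catheter", v)
    _frac(ut.disutility_retreatment, "utilities.disutility_retreatment", v)
    for k, val in ut.disutility_by_ae.items():
        _frac(val, f"utilities.disutility_by_ae[{k}]", v)
    for k, val in ut.recovery_time_by_ae.items():
        _nonneg(val, f"utilities.recovery_time_by_ae[{k}]", v)

    lt = deck.life_table
    if len(lt.ages) == 0:
        v.append(Violation("life_table", (), "life table is empty"))
    else:
        ages = list(lt.ages)
        if ages != sorted(set(ages)):
            v.append(Violation("life_table.ages", ages, "ages must be strictly increasing"))
        for a, q in zip(lt.ages, lt.qx):
            _frac(q, f"life_table.qx[age={a}]", v)
        lo, hi = min(ages), max(ages)
        if deck.strategies:
            need_hi = deck.cohort.start_age + deck.settings.horizon_years - 1
            if lo > deck.cohort.start_age or hi < math.floor(need_hi):
                v.append(Violation("life_table.ages", (lo, hi),
                                   "life table must cover the cohort's age range over the horizon"))
    return v
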