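"""Markov cohort engine.

Runs a treated cohort through the cycle plan (quarterly cycles in year 1,
annual cycles thereafter by default), accumulating discounted costs by
component and discounted quality-adjusted life years, with age-dependent
background mortality from the deck's life table.

Conventions (all configurable via :class:`~bphcea.deck.EconSettings`):

* rewards accrue on survivors at cycle start; discounting is evaluated at the
  cycle's start time, ``(1+r)**(-t)`` with fractional ``t`` for quarterly
  cycles (midpoint when ``half_cycle_correction`` is on);
* death is the only absorbing state;
* retreatment does not reset the symptom trajectory — the published
  trajectories already average over post-retreatment experience;
* concurrent disutility decrements are additive and the per-cycle utility
  rate is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clinical import (
    SeverityDistribution,
    expected_catheter_burden,
    rate_at,
    severity_from_ipss,
    trajectory_at,
)
from .deck import (
    RETREAT_MEDICAL,
    RETREAT_REPEAT,
    InputDeck,
    StrategySpec,
)

__all__ = [
    "COST_COMPONENTS",
    "CycleLedger",
    "CohortTrace",
    "discount_factor",
    "per_cycle_mortality",
    "run_cohort",
]

COST_COMPONENTS = ("procedure", "drug", "followup", "ae", "retreatment", "catheter")


def discount_factor(t: float, rate: float) -> float:
    """Continuous-in-time discount factor (1+rate)^(-t)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if rate <= -1:
        raise ValueError("discount rate must be > -1")
    return (1.0 + rate) ** (-t)


def per_cycle_mortality(q_annual: float, cycle_len: float) -> float:
    """Convert an annual death probability to a cycle-length probability."""
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError("annual death probability must lie in [0, 1]")
    return 1.0 - (1.0 - q_annual) ** cycle_len


@dataclass
class CycleLedger:
    """Per-cycle accounting record for one strategy's cohort."""

    cycle: int
    t_start: float
    t_end: float
    survival_at_start: float
    deaths_in_cycle: float
    severity: SeverityDistribution
    qaly_increment: float
    ly_increment_discounted: float
    ly_increment: float
    cost_increment: float
    cost_components: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortTrace:
    strategy: str
    ledgers: list[CycleLedger]
    total_cost: float
    total_qalys: float
    life_years_discounted: float
    life_years: float
    cost_by_component: dict[str, float]


@dataclass
class _State:
    survival: float = 1.0
    at_risk: float = 1.0       # never-retreated fraction of the alive cohort
    medical_pool: float = 0.0  # fraction managed on retreatment drug therapy
    lt_actives: list = field(default_factory=list)  # [frac, remaining_yrs, profile]


def _periprocedural_package_cost(deck: InputDeck, strategy: StrategySpec) -> float:
    """Expected periprocedural AE + catheter-removal cost of one procedure."""
    cost = 0.0
    for ae in strategy.ae_profiles:
        if ae.category == "periprocedural":
            cost += rate_at(ae.rate_schedule, 0.0) * ae.unit_cost
    cost += (strategy.catheterization_rate
             * strategy.extra_removal_visit_fraction
             * deck.costs.office_visit)
    return cost


def _retreatment_option_cost(deck: InputDeck, strategy: StrategySpec, option: str) -> float:
    """Lump cost of sending one retreated patient to ``option``.

    Surgical options are charged their index treatment cost plus the expected
    periprocedural adverse-event and catheter-removal costs; the medical
    therapy option is charged its two initiation office visits (the ongoing
    drug cost accrues in the medical pool).
    """
    if option == RETREAT_MEDICAL:
        return 2.0 * deck.costs.office_visit
    name = strategy.name if option == RETREAT_REPEAT else option
    base = deck.costs.retreatment_costs.get(name)
    target = None
    try:
        target = deck.strategy(name)
    except KeyError:
        pass
    if base is None:
        if target is None:
            raise KeyError(f"no retreatment cost known for option {name!r}")
        base = target.procedure_cost
    extra = _periprocedural_package_cost(deck, target) if target is not None else 0.0
    return base + extra


def _step_cycle(deck: InputDeck, strategy: StrategySpec, cycle: int,
                t_start: float, cycle_len: float, state: _State) -> CycleLedger:
    if not 0.0 <= state.survival <= 1.0 + 1e-12:
        raise RuntimeError(f"inconsistent state: survival={state.survival}")
    s = deck.settings
    u = deck.utilities
    t_end = t_start + cycle_len
    t_disc = t_start + (cycle_len / 2.0 if s.half_cycle_correction else 0.0)
    df = discount_factor(t_disc, s.discount_rate_annual)
    alive = state.survival

    traj = deck.trajectories[strategy.name]
    mean, sd = trajectory_at(traj, min(t_end, s.horizon_years),
                             rule=s.trajectory_rule, horizon=s.horizon_years)
    sev = severity_from_ipss(
        mean, sd, (s.severity_cutoff_mild, s.severity_cutoff_moderate),
        truncate=s.truncate_ipss)

    comp = {k: 0.0 for k in COST_COMPONENTS}
    decrement_rate = 0.0  # utility decrement per alive person-year this cycle

    is_index_cycle = cycle == 0
    if is_index_cycle:
        if strategy.is_surgical:
            comp["procedure"] += alive * strategy.procedure_cost * df
            cath_qaly, cath_cost = expected_catheter_burden(
                strategy, u, deck.costs, s.days_per_year)
            comp["catheter"] += alive * cath_cost * df
            decrement_rate += cath_qaly / cycle_len
        comp["followup"] += (alive * strategy.followup.first_year_visits
                             * deck.costs.office_visit * df)

    # index drug therapy (daily combination) for the never-retreated pool
    if strategy.drug_cost_per_day > 0:
        comp["drug"] += (alive * state.at_risk * strategy.drug_cost_per_day
                         * s.days_per_year * cycle_len * df)
    # retreatment medical-therapy pool
    if state.medical_pool > 0:
        comp["drug"] += (alive * state.medical_pool
                         * deck.costs.medical_therapy_annual * cycle_len * df)

    # severity-dependent annual follow-up from year 2 onward
    if t_start >= 1.0 - 1e-9:
        comp["followup"] += (alive * sev.expected(deck.costs.followup_by_severity)
                             * cycle_len * df)

    # adverse events
    for ae in strategy.ae_profiles:
        rate = rate_at(ae.rate_schedule, t_start)
        if rate > 0:
            comp["ae"] += alive * rate * ae.unit_cost * df
            if ae.category == "long_term":
                state.lt_actives.append([rate, ae.recovery_time, ae])
            else:
                active = min(ae.recovery_time, cycle_len)
                decrement_rate += rate * ae.disutility * active / cycle_len
    # ongoing long-term events
    for entry in state.lt_actives:
        frac, remaining, ae = entry
        active = min(remaining, cycle_len)
        if active > 0:
            comp["ae"] += alive * frac * ae.annual_cost * active * df
            decrement_rate += frac * ae.disutility * active / cycle_len
        entry[1] = remaining - cycle_len
    state.lt_actives = [e for e in state.lt_actives if e[1] > 1e-12]

    # retreatment of the never-retreated pool
    r_rate = rate_at(strategy.retreatment.rate_schedule, t_start)
    if r_rate > 0 and state.at_risk > 0 and strategy.retreatment.mix:
        moving = state.at_risk * r_rate
        for option, p in strategy.retreatment.mix.items():
            if p <= 0:
                continue
            comp["retreatment"] += (alive * moving * p
                                    * _retreatment_option_cost(deck, strategy, option) * df)
            if option == RETREAT_MEDICAL:
                state.medical_pool += moving * p
        active = min(u.retreatment_disutility_duration, cycle_len)
        decrement_rate += moving * u.disutility_retreatment * active / cycle_len
        state.at_risk -= moving

    utility = sev.expected(u.utility_by_severity)
    utility_eff = max(utility - decrement_rate, 0.0)
    qaly_inc = alive * cycle_len * utility_eff * df
    ly_disc = alive * cycle_len * df
    ly = alive * cycle_len

    q_annual = deck.life_table.annual_q(deck.cohort.start_age + t_start)
    deaths = alive * per_cycle_mortality(q_annual, cycle_len)
    state.survival = alive - deaths

    total = sum(comp.values())
    return CycleLedger(
        cycle=cycle, t_start=t_start, t_end=t_end,
        survival_at_start=alive, deaths_in_cycle=deaths,
        severity=sev, qaly_increment=qaly_inc,
        ly_increment_discounted=ly_disc, ly_increment=ly,
        cost_increment=total, cost_components=comp,
    )


def run_cohort(deck: InputDeck, strategy: str | StrategySpec) -> CohortTrace:
    """Run one strategy's cohort over the full cycle plan.

    Deterministic; returns one :class:`CycleLedger` per cycle plus totals.
    """
    if isinstance(strategy, str):
        strategy = deck.strategy(strategy)
    state = _State()
    ledgers: list[CycleLedger] = []
    t = 0.0
    for i, clen in enumerate(deck.settings.cycle_plan):
        ledgers.append(_step_cycle(deck, strategy, i, t, clen, state))
        t += clen
    comp_tot = {k: sum(l.cost_components[k] for l in ledgers) for k in COST_COMPONENTS}
    return CohortTrace(
        strategy=strategy.name,
        ledgers=ledgers,
        total_cost=sum(l.cost_increment for l in ledgers),
        total_qalys=sum(l.qaly_increment for l in ledgers),
        life_years_discounted=sum(l.ly_increment_discounted for l in ledgers),
        life_years=sum(l.ly_increment for l in ledgers),
        cost_by_component=comp_tot,
    )
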