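"""Shared fixtures: the packaged reference deck and small toy decks."""

from __future__ import annotations

import pytest

from bphcea.deck import (
    AEProfile,
    CohortSpec,
    CostTable,
    EconSettings,
    FollowupSchedule,
    InputDeck,
    IPSSTrajectory,
    LifeTable,
    RetreatmentPolicy,
    StrategySpec,
    UtilityCatalog,
)
from bphcea.synthetic import reference_deck


@pytest.fixture(scope="session")
def ref_deck() -> InputDeck:
    return reference_deck()


@pytest.fixture()
def deck(ref_deck) -> InputDeck:
    """A mutable copy of the reference deck."""
    return ref_deck.copy()


def make_degenerate_deck(n_cycles: int = 8) -> InputDeck:
    """Unit utility everywhere, zero mortality/AEs/costs/discount.

    Under these conditions the accumulated QALYs must equal the horizon
    exactly (5 years by default).
    """
    plan = (0.25,) * 4 + (1.0,) * 4
    settings = EconSettings(discount_rate_annual=0.0, cycle_plan=plan)
    strat = StrategySpec(
        name="X", is_surgical=False, procedure_cost=0.0, drug_cost_per_day=0.0,
        catheterization_rate=0.0,
        retreatment=RetreatmentPolicy(), followup=FollowupSchedule(first_year_visits=0.0))
    traj = IPSSTrajectory("X", times=(0.0, 5.0), means=(22.0, 22.0), sds=(4.8, 4.8))
    return InputDeck(
        settings=settings,
        cohort=CohortSpec(),
        strategies=(strat,),
        trajectories={"X": traj},
        costs=CostTable(office_visit=0.0,
                        followup_by_severity={"mild": 0.0, "moderate": 0.0, "severe": 0.0},
                        medical_therapy_annual=0.0),
        utilities=UtilityCatalog(
            utility_by_severity={"mild": 1.0, "moderate": 1.0, "severe": 1.0},
            disutility_catheter=0.0, disutility_retreatment=0.0),
        life_table=LifeTable(ages=tuple(float(a) for a in range(60, 75)),
                             qx=(0.0,) * 15),
    )


@pytest.fixture()
def degenerate_deck() -> InputDeck:
    return make_degenerate_deck()


def make_toy_two_cycle_deck() -> InputDeck:
    """Tiny two-annual-cycle deck checked against a hand-computed ledger."""
    settings = EconSettings(discount_rate_annual=0.03, horizon_years=2.0,
                            cycle_plan=(1.0, 1.0))
    ae = AEProfile(name="A", category="short_term",
                   rate_schedule=((0.0, 0.2),), unit_cost=50.0,
                   disutility=0.1, recovery_time=0.5)
    strat = StrategySpec(
        name="OP", is_surgical=True, procedure_cost=1000.0,
        catheterization_rate=0.5, catheter_duration_days=36.525,
        extra_removal_visit_fraction=0.5,
        ae_profiles=(ae,),
        retreatment=RetreatmentPolicy(rate_schedule=((1.0, 0.1),),
                                      mix={"medical_therapy": 1.0}),
        followup=FollowupSchedule(first_year_visits=2.0))
    traj = IPSSTrajectory("OP", times=(0.0, 1.0, 2.0),
                          means=(20.0, 10.0, 12.0), sds=(5.0, 6.0, 6.0))
    return InputDeck(
        settings=settings,
        cohort=CohortSpec(start_age=63.0, baseline_ipss_mean=20.0, baseline_ipss_sd=5.0),
        strategies=(strat,),
        trajectories={"OP": traj},
        costs=CostTable(office_visit=100.0,
                        followup_by_severity={"mild": 80.0, "moderate": 100.0,
                                              "severe": 200.0},
                        medical_therapy_annual=120.0),
        utilities=UtilityCatalog(
            utility_by_severity={"mild": 0.9, "moderate": 0.8, "severe": 0.7},
            disutility_catheter=0.2, disutility_by_ae={"A": 0.1},
            recovery_time_by_ae={"A": 0.5},
            disutility_retreatment=0.1, retreatment_disutility_duration=0.5),
        life_table=LifeTable(ages=(62.0, 63.0, 64.0, 65.0),
                             qx=(0.01, 0.01, 0.01, 0.01)),
    )


@pytest.fixture()
def toy_deck() -> InputDeck:
    return make_toy_two_cycle_deck()
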