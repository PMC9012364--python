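"""Input-deck generation: the packaged 2021-Medicare reference deck and a
seeded random deck generator for property testing.

The reference deck encodes the published model inputs for the five BPH
treatment strategies (combination drug therapy CT, prostatic urethral lift
PUL, water vapor thermal therapy WVTT, photoselective vaporization PVP, and
transurethral resection TURP): 2021 Medicare procedure / follow-up / adverse
event costs, the network-meta-analysis IPSS trajectories, catheterization
and 1-year retreatment rates, a 3% discount rate and a $50,000/QALY
willingness-to-pay threshold.

Three component tables were not published at cell level and are shipped as
clearly labelled SYNTHETIC stand-ins (see the files' provenance columns and
``docs/methods.md``): the utility/disutility catalog
(``synthetic_utilities.csv``), the per-cycle adverse-event rate schedules
(``synthetic_ae_rates.csv``), and the male life table
(``synthetic_life_table.csv``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .clinical import extrapolate_ae_rates
from .deck import (
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
    validate_deck,
)
from .io import load_input_deck

__all__ = [
    "reference_deck",
    "reference_deck_path",
    "build_reference_deck",
    "SyntheticConfig",
    "generate_synthetic_deck",
]

# ---------------------------------------------------------------------------
# published inputs (2021 USD; rates as fractions)
# ---------------------------------------------------------------------------

PROCEDURE_COSTS = {"PUL": 7258.0, "WVTT": 1867.0, "PVP": 4813.0, "TURP": 5157.0}
CT_DRUG_COST_PER_DAY = 3.73
MEDICAL_THERAPY_ANNUAL = 105.0
OFFICE_VISIT = 87.0
FOLLOWUP_BY_SEVERITY = {"mild": 87.0, "moderate": 97.0, "severe": 184.0}

AE_UNIT_COSTS = {
    "TUR syndrome": 6554.0,
    "Transfusion": 6554.0,
    "Immediate acute urinary retention": 0.0,
    "Bladder spasm": 87.0,
    "Urinary retention": 174.0,
    "Urinary tract infection": 87.0,
    "Pelvic pain": 87.0,
    "Hematuria": 87.0,
    "Dysuria": 87.0,
    "Urinary urge incontinence": 87.0,
    "Frequency and urgency": 87.0,
    "Encrusted implant": 3285.0,
    "Urethral stricture": 3347.0,
    "Bladder neck contraction": 3179.0,
    "Erectile dysfunction": 0.0,
    "Urinary incontinence": 0.0,
}
AE_ANNUAL_COSTS = {"Erectile dysfunction": 1370.0, "Urinary incontinence": 1354.0}

CATHETERIZATION_RATES = {"PUL": 0.514, "WVTT": 0.904, "PVP": 0.941, "TURP": 0.932}
RETREATMENT_YEAR1 = {"CT": 0.036, "PUL": 0.080, "WVTT": 0.030, "PVP": 0.078,
                     "TURP": 0.063}

# Absolute post-treatment IPSS (mean, SD) on the published grid.
IPSS_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
IPSS_TRAJECTORIES = {
    "CT":   [(22.0, 4.8), (11.0, 6.4), (10.5, 6.2), (11.7, 7.0),
             (11.6, 6.5), (11.9, 6.4), (12.8, 7.7), (12.5, 8.1)],
    "PUL":  [(22.0, 4.8), (10.9, 6.4), (10.5, 6.2), (11.6, 7.0),
             (11.5, 6.5), (11.8, 6.4), (12.7, 7.7), (12.4, 8.1)],
    "WVTT": [(22.0, 4.8), (10.6, 6.4), (9.8, 6.2), (10.3, 6.7),
             (10.2, 6.2), (10.5, 6.1), (11.4, 7.4), (11.1, 7.8)],
    "PVP":  [(22.0, 4.8), (10.1, 6.4), (8.7, 6.2), (8.2, 7.3),
             (8.1, 6.8), (8.4, 6.7), (9.3, 8.0), (9.0, 8.4)],
    "TURP": [(22.0, 4.8), (10.0, 6.4), (8.6, 6.2), (7.9, 7.2),
             (7.8, 6.7), (8.1, 6.6), (9.0, 7.9), (8.7, 8.3)],
}

# --- SYNTHETIC stand-ins (no published cell values available) --------------
# Utilities / disutilities: chosen once from the range used in published BPH
# cost-utility models; catheter durations from trial-report magnitudes.
SYNTHETIC_UTILITIES = {"mild": 0.95, "moderate": 0.90, "severe": 0.80}
SYNTHETIC_DISUTILITY_CATHETER = 0.20
SYNTHETIC_CATHETER_DAYS = {"PUL": 1.0, "WVTT": 3.4, "PVP": 1.9, "TURP": 2.4}
SYNTHETIC_DISUTILITY_RETREATMENT = 0.05
SYNTHETIC_RETREAT_DISUTILITY_DURATION = 0.25

# (disutility, recovery_time_years)
SYNTHETIC_AE_QOL = {
    "TUR syndrome": (0.15, 0.08),
    "Transfusion": (0.10, 0.05),
    "Immediate acute urinary retention": (0.10, 0.06),
    "Bladder spasm": (0.05, 0.10),
    "Urinary retention": (0.10, 0.12),
    "Urinary tract infection": (0.07, 0.08),
    "Pelvic pain": (0.07, 0.15),
    "Hematuria": (0.05, 0.08),
    "Dysuria": (0.05, 0.10),
    "Urinary urge incontinence": (0.08, 0.25),
    "Frequency and urgency": (0.05, 0.25),
    "Encrusted implant": (0.08, 0.25),
    "Urethral stricture": (0.10, 0.30),
    "Bladder neck contraction": (0.10, 0.30),
    "Erectile dysfunction": (0.12, 100.0),
    "Urinary incontinence": (0.11, 100.0),
}

# Synthetic per-cycle AE incidence schedules (time at cycle start -> rate),
# shaped like trial safety tables: a peak in the index quarter decaying over
# year 1, rare structural complications appearing in years 1-2.
SYNTHETIC_AE_SCHEDULES: dict[str, dict[str, tuple[str, list[tuple[float, float]]]]] = {
    "CT": {
        "Erectile dysfunction": ("long_term",
                                 [(0.0, 0.00375), (0.25, 0.00375), (0.5, 0.00375),
                                  (0.75, 0.00375), (1.0, 0.015), (2.0, 0.015),
                                  (3.0, 0.015), (4.0, 0.015)]),
    },
    "PUL": {
        "Immediate acute urinary retention": ("periprocedural", [(0.0, 0.05)]),
        "Hematuria": ("short_term", [(0.0, 0.18), (0.25, 0.05), (0.5, 0.01)]),
        "Dysuria": ("short_term", [(0.0, 0.17), (0.25, 0.06), (0.5, 0.02)]),
        "Pelvic pain": ("short_term", [(0.0, 0.12), (0.25, 0.04), (0.5, 0.01)]),
        "Frequency and urgency": ("short_term", [(0.0, 0.05), (0.25, 0.02)]),
        "Urinary tract infection": ("short_term", [(0.0, 0.02), (0.25, 0.01)]),
        "Encrusted implant": ("short_term", [(1.0, 0.005), (2.0, 0.005),
                                             (3.0, 0.005), (4.0, 0.005)]),
        "Urethral stricture": ("short_term", [(1.0, 0.003), (2.0, 0.003),
                                              (3.0, 0.003), (4.0, 0.003)]),
    },
    "WVTT": {
        "Immediate acute urinary retention": ("periprocedural", [(0.0, 0.037)]),
        "Dysuria": ("short_term", [(0.0, 0.12), (0.25, 0.04), (0.5, 0.01)]),
        "Hematuria": ("short_term", [(0.0, 0.08), (0.25, 0.03), (0.5, 0.01)]),
        "Frequency and urgency": ("short_term", [(0.0, 0.04), (0.25, 0.015)]),
        "Urinary tract infection": ("short_term", [(0.0, 0.025), (0.25, 0.01)]),
        "Urinary retention": ("short_term", [(0.0, 0.025), (0.25, 0.005)]),
    },
    "PVP": {
        "Transfusion": ("periprocedural", [(0.0, 0.005)]),
        "Immediate acute urinary retention": ("periprocedural", [(0.0, 0.05)]),
        "Hematuria": ("short_term", [(0.0, 0.09), (0.25, 0.03), (0.5, 0.01)]),
        "Dysuria": ("short_term", [(0.0, 0.08), (0.25, 0.03), (0.5, 0.01)]),
        "Urinary tract infection": ("short_term", [(0.0, 0.05), (0.25, 0.02)]),
        "Urinary retention": ("short_term", [(0.0, 0.03), (0.25, 0.01)]),
        "Urethral stricture": ("short_term", [(1.0, 0.01), (2.0, 0.005)]),
        "Bladder neck contraction": ("short_term", [(1.0, 0.01), (2.0, 0.005)]),
        "Erectile dysfunction": ("long_term", [(0.0, 0.0125), (0.25, 0.0125),
                                               (0.5, 0.0125), (0.75, 0.0125)]),
        "Urinary incontinence": ("long_term", [(0.0, 0.0025), (0.25, 0.0025),
                                               (0.5, 0.0025), (0.75, 0.0025)]),
    },
    "TURP": {
        "TUR syndrome": ("periprocedural", [(0.0, 0.014)]),
        "Transfusion": ("periprocedural", [(0.0, 0.02)]),
        "Hematuria": ("short_term", [(0.0, 0.10), (0.25, 0.04), (0.5, 0.01)]),
        "Dysuria": ("short_term", [(0.0, 0.08), (0.25, 0.03), (0.5, 0.01)]),
        "Urinary tract infection": ("short_term", [(0.0, 0.06), (0.25, 0.02)]),
        "Urinary retention": ("short_term", [(0.0, 0.04), (0.25, 0.01)]),
        "Urethral stricture": ("short_term", [(1.0, 0.02), (2.0, 0.01)]),
        "Bladder neck contraction": ("short_term", [(1.0, 0.015), (2.0, 0.0075)]),
        "Erectile dysfunction": ("long_term", [(0.0, 0.01625), (0.25, 0.01625),
                                               (0.5, 0.01625), (0.75, 0.01625)]),
        "Urinary incontinence": ("long_term", [(0.0, 0.005), (0.25, 0.005),
                                               (0.5, 0.005), (0.75, 0.005)]),
    },
}

# Synthetic male life table (annual death probability by age); magnitudes of
# recent US male national life tables, labelled synthetic because no rates
# were published with the model inputs.
SYNTHETIC_LIFE_TABLE = {
    60: 0.0112, 61: 0.0120, 62: 0.0128, 63: 0.0137, 64: 0.0146, 65: 0.0157,
    66: 0.0170, 67: 0.0183, 68: 0.0197, 69: 0.0214, 70: 0.0232,
}

# Default retreatment destination mixes (the published option set without
# published proportions): drug-therapy failures go to the cheaper MIST;
# procedure failures go to symptom-managing medical therapy.
DEFAULT_RETREAT_MIX = {
    "CT": {"WVTT": 1.0},
    "PUL": {"medical_therapy": 1.0},
    "WVTT": {"medical_therapy": 1.0},
    "PVP": {"medical_therapy": 1.0},
    "TURP": {"medical_therapy": 1.0},
}

CYCLE_STARTS = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0)


def _retreat_schedule(year1_rate: float, post_year1_annual: float | None = None
                      ) -> tuple[tuple[float, float], ...]:
    """Quarterly per-cycle rates in year 1 (compounding to the 1-year rate),
    then a constant annual rate (the annualized year-1 rate by default)."""
    q = 1.0 - (1.0 - year1_rate) ** 0.25
    annual = year1_rate if post_year1_annual is None else post_year1_annual
    sched = [(t, q) for t in (0.0, 0.25, 0.5, 0.75)]
    sched += [(t, annual) for t in (1.0, 2.0, 3.0, 4.0)]
    return tuple(sched)


def build_reference_deck() -> InputDeck:
    """Construct the reference deck programmatically (single source of the
    packaged CSV deck; the two must stay identical)."""
    ae_costs = dict(AE_UNIT_COSTS)
    for k, v in AE_ANNUAL_COSTS.items():
        ae_costs[k + "/annual"] = v
    costs = CostTable(
        office_visit=OFFICE_VISIT,
        followup_by_severity=dict(FOLLOWUP_BY_SEVERITY),
        medical_therapy_annual=MEDICAL_THERAPY_ANNUAL,
        ae_costs=ae_costs,
        retreatment_costs=dict(PROCEDURE_COSTS),
    )
    utilities = UtilityCatalog(
        utility_by_severity=dict(SYNTHETIC_UTILITIES),
        disutility_catheter=SYNTHETIC_DISUTILITY_CATHETER,
        disutility_by_ae={k: v[0] for k, v in SYNTHETIC_AE_QOL.items()},
        recovery_time_by_ae={k: v[1] for k, v in SYNTHETIC_AE_QOL.items()},
        disutility_retreatment=SYNTHETIC_DISUTILITY_RETREATMENT,
        retreatment_disutility_duration=SYNTHETIC_RETREAT_DISUTILITY_DURATION,
    )
    strategies = []
    for name in ("CT", "PUL", "WVTT", "PVP", "TURP"):
        profiles = []
        for ae_name, (category, observed) in sorted(SYNTHETIC_AE_SCHEDULES[name].items()):
            sched = observed
            if category != "periprocedural":
                sched = extrapolate_ae_rates(observed, list(CYCLE_STARTS))
            profiles.append(AEProfile(
                name=ae_name, category=category,
                rate_schedule=tuple(sched),
                unit_cost=AE_UNIT_COSTS[ae_name],
                annual_cost=AE_ANNUAL_COSTS.get(ae_name, 0.0),
                disutility=SYNTHETIC_AE_QOL[ae_name][0],
                recovery_time=SYNTHETIC_AE_QOL[ae_name][1],
            ))
        surgical = name != "CT"
        strategies.append(StrategySpec(
            name=name,
            is_surgical=surgical,
            procedure_cost=PROCEDURE_COSTS.get(name, 0.0),
            drug_cost_per_day=CT_DRUG_COST_PER_DAY if name == "CT" else 0.0,
            catheterization_rate=CATHETERIZATION_RATES.get(name, 0.0),
            catheter_duration_days=SYNTHETIC_CATHETER_DAYS.get(name, 0.0),
            extra_removal_visit_fraction=0.5,
            ae_profiles=tuple(profiles),
            retreatment=RetreatmentPolicy(
                rate_schedule=_retreat_schedule(RETREATMENT_YEAR1[name]),
                mix=dict(DEFAULT_RETREAT_MIX[name]),
            ),
            followup=FollowupSchedule(first_year_visits=2.0),
        ))
    trajectories = {
        name: IPSSTrajectory(
            strategy=name,
            times=IPSS_GRID,
            means=tuple(m for m, _ in pts),
            sds=tuple(s for _, s in pts),
        )
        for name, pts in IPSS_TRAJECTORIES.items()
    }
    ages = sorted(SYNTHETIC_LIFE_TABLE)
    deck = InputDeck(
        settings=EconSettings(),
        cohort=CohortSpec(),
        strategies=tuple(strategies),
        trajectories=trajectories,
        costs=costs,
        utilities=utilities,
        life_table=LifeTable(ages=tuple(float(a) for a in ages),
                             qx=tuple(SYNTHETIC_LIFE_TABLE[a] for a in ages)),
        provenance={
            "deck": "2021 US Medicare BPH cost-utility reference deck",
            "costs": "published 2021 Medicare reimbursement inputs",
            "trajectories": "published random-effects NMA IPSS table",
            "utilities": "SYNTHETIC stand-in values (catalog not published at "
                         "cell level); see synthetic_utilities.csv",
            "ae_rates": "SYNTHETIC stand-in schedules; see synthetic_ae_rates.csv",
            "life_table": "SYNTHETIC male life table; see synthetic_life_table.csv",
        },
    )
    violations = validate_deck(deck)
    if violations:  # construction bug guard; not reachable for shipped values
        raise AssertionError("reference deck invalid: " +
                             "; ".join(str(v) for v in violations))
    return deck


def reference_deck_path() -> Path:
    """Path of the packaged reference deck manifest."""
    return Path(resources.files("bphcea") / "data" / "medicare2021" / "deck.yaml")


def reference_deck() -> InputDeck:
    """Load the packaged 2021-Medicare reference deck."""
    return load_input_deck(reference_deck_path())


# ---------------------------------------------------------------------------
# random deck generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Ranges for the random deck generator.

    Generated decks mirror the structure of the reference deck: one drug
    therapy plus ``n_strategies - 1`` procedures, dip-then-drift symptom
    trajectories, index-cycle-only periprocedural events, and a log-linear
    male life table.
    """

    rng_seed: int = 0
    n_strategies: int = 4
    procedure_cost_range: tuple[float, float] = (1000.0, 9000.0)
    drug_cost_per_day_range: tuple[float, float] = (1.0, 6.0)
    utility_severe_range: tuple[float, float] = (0.6, 0.85)
    utility_step_range: tuple[float, float] = (0.02, 0.10)
    ipss_improvement_range: tuple[float, float] = (8.0, 16.0)
    ipss_drift_range: tuple[float, float] = (-0.5, 1.0)
    ipss_sd_range: tuple[float, float] = (4.0, 8.0)
    n_ae_range: tuple[int, int] = (1, 4)
    ae_rate_range: tuple[float, float] = (0.005, 0.2)
    ae_cost_range: tuple[float, float] = (50.0, 5000.0)
    retreat_year1_range: tuple[float, float] = (0.01, 0.12)
    catheter_rate_range: tuple[float, float] = (0.3, 1.0)
    life_table_q60: float = 0.011
    life_table_slope: float = 0.075  # proportional increase per year of age
    baseline_ipss: tuple[float, float] = (22.0, 4.8)
    start_age: float = 63.0


def generate_synthetic_deck(config: SyntheticConfig | None = None) -> InputDeck:
    """Generate a structurally valid random input deck (deterministic per seed).

    Every generated deck passes :func:`~bphcea.deck.validate_deck`; symptom
    trajectories improve sharply by 3 months and then drift within bounds.
    """
    cfg = config or SyntheticConfig()
    if cfg.n_strategies < 2:
        raise ValueError("need at least 2 strategies")
    for name in ("procedure_cost_range", "ae_rate_range", "retreat_year1_range"):
        lo, hi = getattr(cfg, name)
        if lo > hi or lo < 0:
            raise ValueError(f"infeasible range {name}: ({lo}, {hi})")
    if cfg.ae_rate_range[1] > 1:
        raise ValueError("AE rates must stay within [0, 1]")
    rng = np.random.default_rng(cfg.rng_seed)

    u_sev = rng.uniform(*cfg.utility_severe_range)
    u_mod = min(u_sev + rng.uniform(*cfg.utility_step_range), 0.99)
    u_mild = min(u_mod + rng.uniform(*cfg.utility_step_range), 1.0)

    base_mean, base_sd = cfg.baseline_ipss
    names = [f"S{i}" for i in range(cfg.n_strategies)]
    ae_names = [f"AE{i}" for i in range(8)]
    ae_costs = {n: float(rng.uniform(*cfg.ae_cost_range)) for n in ae_names}
    ae_dis = {n: float(rng.uniform(0.02, 0.15)) for n in ae_names}
    ae_rec = {n: float(rng.uniform(0.05, 0.45)) for n in ae_names}

    costs = CostTable(
        office_visit=float(rng.uniform(50, 150)),
        followup_by_severity=dict(zip(
            ("mild", "moderate", "severe"),
            sorted(rng.uniform(50, 250, size=3)))),
        medical_therapy_annual=float(rng.uniform(80, 200)),
        ae_costs=dict(ae_costs),
        retreatment_costs={},
    )
    utilities = UtilityCatalog(
        utility_by_severity={"mild": float(u_mild), "moderate": float(u_mod),
                             "severe": float(u_sev)},
        disutility_catheter=float(rng.uniform(0.05, 0.35)),
        disutility_by_ae=dict(ae_dis),
        recovery_time_by_ae=dict(ae_rec),
        disutility_retreatment=float(rng.uniform(0.0, 0.1)),
    )

    strategies = []
    trajectories = {}
    surgical_names = names[1:]
    for i, name in enumerate(names):
        surgical = i > 0
        n_ae = int(rng.integers(cfg.n_ae_range[0], cfg.n_ae_range[1] + 1))
        chosen = rng.choice(ae_names, size=n_ae, replace=False)
        profiles = []
        for j, ae_name in enumerate(chosen):
            if surgical and j == 0:
                category = "periprocedural"
                sched = ((0.0, float(rng.uniform(*cfg.ae_rate_range))),)
            else:
                category = "short_term" if ae_rec[ae_name] <= 0.5 else "long_term"
                r0 = float(rng.uniform(*cfg.ae_rate_range))
                sched = tuple((t, max(r0 * (0.5 ** k), 0.0))
                              for k, t in enumerate((0.0, 0.25, 0.5)))
            profiles.append(AEProfile(
                name=str(ae_name), category=category, rate_schedule=sched,
                unit_cost=ae_costs[ae_name],
                annual_cost=float(rng.uniform(0, 1500)) if category == "long_term" else 0.0,
                disutility=ae_dis[ae_name], recovery_time=ae_rec[ae_name]))
        if surgical:
            mix = {"medical_therapy": 1.0}
        else:
            mix = {str(rng.choice(surgical_names)): 1.0}
        strategies.append(StrategySpec(
            name=name,
            is_surgical=surgical,
            procedure_cost=float(rng.uniform(*cfg.procedure_cost_range)) if surgical else 0.0,
            drug_cost_per_day=0.0 if surgical else float(
                rng.uniform(*cfg.drug_cost_per_day_range)),
            catheterization_rate=float(rng.uniform(*cfg.catheter_rate_range))
            if surgical else 0.0,
            catheter_duration_days=float(rng.uniform(0.5, 5.0)) if surgical else 0.0,
            ae_profiles=tuple(profiles),
            retreatment=RetreatmentPolicy(
                rate_schedule=_retreat_schedule(float(rng.uniform(*cfg.retreat_year1_range))),
                mix=mix),
            followup=FollowupSchedule(first_year_visits=2.0),
        ))
        # dip-then-drift trajectory: sharp improvement by 3 months, small
        # further dip at 6 months, bounded drift upward afterwards
        improvement = float(rng.uniform(*cfg.ipss_improvement_range))
        m3 = base_mean - improvement
        m6 = m3 - abs(float(rng.uniform(0, 1.5)))
        means = [base_mean, m3, m6]
        m = m6
        for _ in range(5):
            m = m + float(rng.uniform(*cfg.ipss_drift_range))
            means.append(m)
        means = [float(np.clip(v, 0.5, 35.0)) for v in means]
        means[0] = base_mean
        sds = [base_sd] + [float(rng.uniform(*cfg.ipss_sd_range)) for _ in range(7)]
        trajectories[name] = IPSSTrajectory(
            strategy=name, times=IPSS_GRID, means=tuple(means), sds=tuple(sds))

    ages = list(range(int(cfg.start_age) - 3, int(cfg.start_age) + 8))
    qx = [min(cfg.life_table_q60 * (1 + cfg.life_table_slope) ** (a - 60), 1.0)
          for a in ages]
    deck = InputDeck(
        settings=EconSettings(reference_strategy=names[0]),
        cohort=CohortSpec(start_age=cfg.start_age, baseline_ipss_mean=base_mean,
                          baseline_ipss_sd=base_sd),
        strategies=tuple(strategies),
        trajectories=trajectories,
        costs=costs,
        utilities=utilities,
        life_table=LifeTable(ages=tuple(float(a) for a in ages), qx=tuple(qx)),
        provenance={"deck": f"synthetic deck, seed {cfg.rng_seed}"},
    )
    violations = validate_deck(deck)
    if violations:
        raise ValueError("generated deck invalid: " +
                         "; ".join(str(v) for v in violations))
    return deck
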