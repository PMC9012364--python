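"""Deck serialization: manifest + delimited component tables, result export.

A deck on disk is a YAML manifest (``deck.yaml``) holding the scalar settings
and the names of six component tables::

    strategies.csv         name, is_surgical, procedure_cost, ...
    ipss_trajectories.csv  strategy, time_years, ipss_mean, ipss_sd
    ae_rates.csv           strategy, ae_name, category, time_years, rate
    costs.csv              item, kind, value
    utilities.csv          item, kind, value
    life_table.csv         age, qx

Loading resolves all cross-references (AE unit costs and disutilities are
looked up from the cost/utility catalogs) and rejects unknown manifest keys.
``save_deck`` followed by ``load_input_deck`` is the identity on valid decks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

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

__all__ = ["load_input_deck", "save_deck", "export_results", "DeckError"]

DECK_VERSION = 1

_MANIFEST_KEYS = {"deck_version", "settings", "cohort", "tables", "provenance"}
_TABLE_KEYS = {"strategies", "ipss_trajectories", "ae_rates", "costs",
               "utilities", "life_table"}


class DeckError(ValueError):
    """Raised on schema violations while reading a deck."""


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DeckError(f"{fname}: missing columns {missing}")


def _parse_mix(text: str) -> dict[str, float]:
    """Parse ``"WVTT:1.0"`` / ``"medical_therapy:0.6;TURP:0.4"``."""
    mix: dict[str, float] = {}
    text = (text or "").strip()
    if not text:
        return mix
    for part in text.split(";"):
        k, _, val = part.partition(":")
        mix[k.strip()] = float(val)
    return mix


def _format_mix(mix: dict[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in mix.items())


def _parse_schedule(text: str) -> tuple[tuple[float, float], ...]:
    """Parse ``"0:0.0091;0.25:0.0091"`` into a (time, rate) schedule."""
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        t, _, r = part.partition(":")
        out.append((float(t), float(r)))
    return tuple(out)


def _format_schedule(sched) -> str:
    return ";".join(f"{t!r}:{r!r}" for t, r in sched)


def load_input_deck(path: str | Path) -> InputDeck:
    """Read a deck manifest (or a directory containing ``deck.yaml``).

    Raises
    ------
    FileNotFoundError
        if the manifest or a referenced table is absent.
    DeckError
        on schema violations (unknown keys, missing columns, bad values),
        naming the offending field.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "deck.yaml"
    if not path.exists():
        raise FileNotFoundError(f"deck manifest not found: {path}")
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise DeckError(f"{path}: manifest must be a mapping")
    unknown = set(manifest) - _MANIFEST_KEYS
    if unknown:
        raise DeckError(f"{path}: unknown manifest keys {sorted(unknown)}")
    tables = manifest.get("tables", {})
    unknown = set(tables) - _TABLE_KEYS
    if unknown:
        raise DeckError(f"{path}: unknown table keys {sorted(unknown)}")
    base = path.parent

    def table(key: str) -> pd.DataFrame:
        fname = tables.get(key, f"{key}.csv")
        fpath = base / fname
        if not fpath.exists():
            raise FileNotFoundError(f"deck table not found: {fpath}")
        return pd.read_csv(fpath, comment="#")

    settings_kw = dict(manifest.get("settings", {}))
    if "cycle_plan" in settings_kw:
        settings_kw["cycle_plan"] = tuple(float(c) for c in settings_kw["cycle_plan"])
    known = {f.name for f in dataclasses.fields(EconSettings)}
    unknown = set(settings_kw) - known
    if unknown:
        raise DeckError(f"{path}: unknown settings keys {sorted(unknown)}")
    settings = EconSettings(**settings_kw)

    cohort_kw = dict(manifest.get("cohort", {}))
    known = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(cohort_kw) - known
    if unknown:
        raise DeckError(f"{path}: unknown cohort keys {sorted(unknown)}")
    cohort = CohortSpec(**cohort_kw)

    # --- catalogs first (cross-referenced by strategies) -------------------
    cdf = table("costs")
    _require_columns(cdf, ["item", "kind", "value"], "costs.csv")
    costs = CostTable(ae_costs={}, retreatment_costs={})
    for _, row in cdf.iterrows():
        kind, item, value = row["kind"], row["item"], float(row["value"])
        if kind == "office_visit":
            costs.office_visit = value
        elif kind == "followup_by_severity":
            costs.followup_by_severity[item] = value
        elif kind == "medical_therapy_annual":
            costs.medical_therapy_annual = value
        elif kind == "ae_unit":
            costs.ae_costs[item] = value
        elif kind == "ae_annual":
            costs.ae_costs[item + "/annual"] = value
        elif kind == "retreatment":
            costs.retreatment_costs[item] = value
        else:
            raise DeckError(f"costs.csv: unknown kind {kind!r} (item {item!r})")

    udf = table("utilities")
    _require_columns(udf, ["item", "kind", "value"], "utilities.csv")
    utilities = UtilityCatalog(disutility_by_ae={}, recovery_time_by_ae={})
    for _, row in udf.iterrows():
        kind, item, value = row["kind"], row["item"], float(row["value"])
        if kind == "utility_severity":
            utilities.utility_by_severity[item] = value
        elif kind == "disutility_ae":
            utilities.disutility_by_ae[item] = value
        elif kind == "recovery_time_ae":
            utilities.recovery_time_by_ae[item] = value
        elif kind == "disutility_catheter":
            utilities.disutility_catheter = value
        elif kind == "disutility_retreatment":
            utilities.disutility_retreatment = value
        elif kind == "retreatment_disutility_duration":
            utilities.retreatment_disutility_duration = value
        else:
            raise DeckError(f"utilities.csv: unknown kind {kind!r} (item {item!r})")

    adf = table("ae_rates")
    _require_columns(adf, ["strategy", "ae_name", "category", "time_years", "rate"],
                     "ae_rates.csv")

    sdf = table("strategies")
    _require_columns(sdf, ["name", "is_surgical", "procedure_cost"], "strategies.csv")
    strategies = []
    for _, row in sdf.iterrows():
        name = str(row["name"])
        profiles = []
        sub = adf[adf["strategy"] == name]
        for ae_name, grp in sub.groupby("ae_name", sort=True):
            cats = grp["category"].unique()
            if len(cats) != 1:
                raise DeckError(f"ae_rates.csv: {name}/{ae_name}: inconsistent category")
            category = str(cats[0])
            sched = tuple(sorted((float(t), float(r))
                                 for t, r in zip(grp["time_years"], grp["rate"])))
            profiles.append(AEProfile(
                name=str(ae_name), category=category, rate_schedule=sched,
                unit_cost=costs.ae_costs.get(str(ae_name), 0.0),
                annual_cost=costs.ae_costs.get(str(ae_name) + "/annual", 0.0),
                disutility=utilities.disutility_by_ae.get(str(ae_name), 0.0),
                recovery_time=utilities.recovery_time_by_ae.get(str(ae_name), 0.25),
            ))
        retreat = RetreatmentPolicy(
            rate_schedule=_parse_schedule(str(row.get("retreat_schedule", "") or "")),
            mix=_parse_mix(str(row.get("retreat_mix", "") or "")),
        )
        followup = FollowupSchedule(
            first_year_visits=float(row.get("first_year_visits", 2.0)),
        )
        strategies.append(StrategySpec(
            name=name,
            is_surgical=bool(row["is_surgical"]) if not isinstance(row["is_surgical"], str)
            else row["is_surgical"].strip().lower() in ("true", "1", "yes"),
            procedure_cost=float(row["procedure_cost"]),
            drug_cost_per_day=float(row.get("drug_cost_per_day", 0.0)),
            catheterization_rate=float(row.get("catheterization_rate", 0.0)),
            catheter_duration_days=float(row.get("catheter_duration_days", 0.0)),
            extra_removal_visit_fraction=float(row.get("extra_removal_visit_fraction", 0.5)),
            ae_profiles=tuple(profiles),
            retreatment=retreat,
            followup=followup,
        ))

    tdf = table("ipss_trajectories")
    _require_columns(tdf, ["strategy", "time_years", "ipss_mean", "ipss_sd"],
                     "ipss_trajectories.csv")
    trajectories = {}
    for name, grp in tdf.groupby("strategy", sort=True):
        grp = grp.sort_values("time_years")
        trajectories[str(name)] = IPSSTrajectory(
            strategy=str(name),
            times=tuple(float(t) for t in grp["time_years"]),
            means=tuple(float(m) for m in grp["ipss_mean"]),
            sds=tuple(float(s) for s in grp["ipss_sd"]),
        )

    ldf = table("life_table")
    _require_columns(ldf, ["age", "qx"], "life_table.csv")
    ldf = ldf.sort_values("age")
    life = LifeTable(ages=tuple(float(a) for a in ldf["age"]),
                     qx=tuple(float(q) for q in ldf["qx"]))

    deck = InputDeck(
        settings=settings, cohort=cohort, strategies=tuple(strategies),
        trajectories=trajectories, costs=costs, utilities=utilities,
        life_table=life, provenance=dict(manifest.get("provenance", {})),
    )
    violations = validate_deck(deck)
    if violations:
        raise DeckError("deck validation failed:\n" +
                        "\n".join(f"  - {v}" for v in violations))
    return deck


def save_deck(deck: InputDeck, directory: str | Path) -> Path:
    """Write a deck as manifest + component tables; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    srows = []
    arows = []
    for st in deck.strategies:
        srows.append({
            "name": st.name,
            "is_surgical": st.is_surgical,
            "procedure_cost": st.procedure_cost,
            "drug_cost_per_day": st.drug_cost_per_day,
            "catheterization_rate": st.catheterization_rate,
            "catheter_duration_days": st.catheter_duration_days,
            "extra_removal_visit_fraction": st.extra_removal_visit_fraction,
            "first_year_visits": st.followup.first_year_visits,
            "retreat_schedule": _format_schedule(st.retreatment.rate_schedule),
            "retreat_mix": _format_mix(st.retreatment.mix),
        })
        for ae in st.ae_profiles:
            for t, r in ae.rate_schedule:
                arows.append({"strategy": st.name, "ae_name": ae.name,
                              "category": ae.category, "time_years": t, "rate": r})
    pd.DataFrame(srows).to_csv(directory / "strategies.csv", index=False)
    cols = ["strategy", "ae_name", "category", "time_years", "rate"]
    pd.DataFrame(arows, columns=cols).to_csv(directory / "ae_rates.csv", index=False)

    trows = []
    for name in sorted(deck.trajectories):
        tr = deck.trajectories[name]
        for t, m, s in zip(tr.times, tr.means, tr.sds):
            trows.append({"strategy": name, "time_years": t,
                          "ipss_mean": m, "ipss_sd": s})
    pd.DataFrame(trows).to_csv(directory / "ipss_trajectories.csv", index=False)

    crows = [{"item": "office_visit", "kind": "office_visit",
              "value": deck.costs.office_visit},
             {"item": "medical_therapy", "kind": "medical_therapy_annual",
              "value": deck.costs.medical_therapy_annual}]
    for sev, val in deck.costs.followup_by_severity.items():
        crows.append({"item": sev, "kind": "followup_by_severity", "value": val})
    for name, val in deck.costs.ae_costs.items():
        if name.endswith("/annual"):
            crows.append({"item": name[:-len("/annual")], "kind": "ae_annual", "value": val})
        else:
            crows.append({"item": name, "kind": "ae_unit", "value": val})
    for name, val in deck.costs.retreatment_costs.items():
        crows.append({"item": name, "kind": "retreatment", "value": val})
    pd.DataFrame(crows).to_csv(directory / "costs.csv", index=False)

    urows = []
    for sev, val in deck.utilities.utility_by_severity.items():
        urows.append({"item": sev, "kind": "utility_severity", "value": val})
    for name, val in deck.utilities.disutility_by_ae.items():
        urows.append({"item": name, "kind": "disutility_ae", "value": val})
    for name, val in deck.utilities.recovery_time_by_ae.items():
        urows.append({"item": name, "kind": "recovery_time_ae", "value": val})
    urows.append({"item": "catheter", "kind": "disutility_catheter",
                  "value": deck.utilities.disutility_catheter})
    urows.append({"item": "retreatment", "kind": "disutility_retreatment",
                  "value": deck.utilities.disutility_retreatment})
    urows.append({"item": "retreatment", "kind": "retreatment_disutility_duration",
                  "value": deck.utilities.retreatment_disutility_duration})
    pd.DataFrame(urows).to_csv(directory / "utilities.csv", index=False)

    pd.DataFrame({"age": deck.life_table.ages, "qx": deck.life_table.qx}) \
        .to_csv(directory / "life_table.csv", index=False)

    manifest = {
        "deck_version": DECK_VERSION,
        "settings": {
            "discount_rate_annual": deck.settings.discount_rate_annual,
            "wtp_threshold": deck.settings.wtp_threshold,
            "horizon_years": deck.settings.horizon_years,
            "cycle_plan": list(deck.settings.cycle_plan),
            "reference_strategy": deck.settings.reference_strategy,
            "half_cycle_correction": deck.settings.half_cycle_correction,
            "severity_cutoff_mild": deck.settings.severity_cutoff_mild,
            "severity_cutoff_moderate": deck.settings.severity_cutoff_moderate,
            "truncate_ipss": deck.settings.truncate_ipss,
            "trajectory_rule": deck.settings.trajectory_rule,
            "days_per_year": deck.settings.days_per_year,
        },
        "cohort": dataclasses.asdict(deck.cohort),
        "tables": {k: f"{k}.csv" for k in sorted(_TABLE_KEYS)},
        "provenance": deck.provenance,
    }
    mpath = directory / "deck.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def _round_display(value: float, kind: str) -> str:
    """Display rounding: whole dollars for currency, 3 decimals for QALYs."""
    if kind == "currency":
        return f"{value:.0f}"
    return f"{value:.3f}"


def export_results(result, path: str | Path, format: str = "csv") -> Path:
    """Write a CEA or uncertainty result to ``path``.

    Persisted numbers are unrounded floats; a rounded display column is
    appended (whole dollars for currency, three decimals for QALYs).
    """
    from .economics import CEAResult

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, CEAResult):
        rows = []
        for r in result.rows:
            rows.append({
                "strategy": r.name,
                "total_cost": r.cost,
                "total_qalys": r.qalys,
                "incremental_cost": r.incremental_cost,
                "incremental_qalys": r.incremental_qalys,
                "icer": r.icer,
                "label": r.label,
                "on_frontier": r.name in result.frontier,
                "frontier_icer": result.frontier_icers.get(r.name),
                "wtp_verdict": r.verdict(result.wtp_threshold),
                "total_cost_display": _round_display(r.cost, "currency"),
                "total_qalys_display": _round_display(r.qalys, "qaly"),
            })
        df = pd.DataFrame(rows)
    elif isinstance(result, pd.DataFrame):
        df = result
    elif hasattr(result, "to_frame"):
        df = result.to_frame()
    else:
        raise TypeError(f"cannot export object of type {type(result).__name__}")

    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, default=str)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
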