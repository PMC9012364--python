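"""Deck validation, serialization round-trip, and result export."""

from __future__ import annotations

import json

import pandas as pd
import pytest
import yaml

from bphcea.deck import validate_deck
from bphcea.economics import StrategyTotals, incremental_analysis
from bphcea.io import DeckError, export_results, load_input_deck, save_deck
from bphcea.synthetic import build_reference_deck, reference_deck_path


class TestValidateDeck:
    def test_reference_deck_is_clean(self, ref_deck):
        assert validate_deck(ref_deck) == []

    def test_negative_procedure_cost_flagged(self, deck):
        deck.strategy("TURP").procedure_cost = -1.0
        v = validate_deck(deck)
        assert any("procedure_cost" in x.field for x in v)

    def test_mix_must_sum_to_one(self, deck):
        deck.strategy("PUL").retreatment.mix = {"medical_therapy": 0.5,
                                                "repeat_same": 0.3}
        v = validate_deck(deck)
        assert any("mix" in x.field for x in v)

    def test_retreatment_never_less_invasive(self, deck):
        # TURP failures cannot step down to a minimally invasive option
        deck.strategy("TURP").retreatment.mix = {"WVTT": 1.0}
        v = validate_deck(deck)
        assert any("less invasive" in x.rule for x in v)

    def test_drug_therapy_failures_move_to_procedure(self, deck):
        deck.strategy("CT").retreatment.mix = {"medical_therapy": 1.0}
        v = validate_deck(deck)
        assert any("procedure" in x.rule for x in v)

    def test_drug_therapy_failures_stay_minimally_invasive(self, deck):
        deck.strategy("CT").retreatment.mix = {"TURP": 1.0}
        v = validate_deck(deck)
        assert any("minimally invasive" in x.rule for x in v)

    def test_cycle_plan_must_sum_to_horizon(self, deck):
        deck.settings.cycle_plan = (0.25, 0.25, 1.0)
        v = validate_deck(deck)
        assert any("cycle_plan" in x.field for x in v)

    def test_utility_ordering_enforced(self, deck):
        deck.utilities.utility_by_severity["severe"] = 0.99
        v = validate_deck(deck)
        assert any("ordered" in x.rule for x in v)

    def test_time_zero_point_must_match_baseline(self, deck):
        tr = deck.trajectories["CT"]
        tr.means = (15.0,) + tr.means[1:]
        v = validate_deck(deck)
        assert any("baseline" in x.rule for x in v)

    def test_life_table_must_cover_horizon(self, deck):
        deck.life_table.ages = deck.life_table.ages[:2]
        deck.life_table.qx = deck.life_table.qx[:2]
        v = validate_deck(deck)
        assert any("life_table" in x.field for x in v)

    def test_periprocedural_rates_only_at_index(self, deck):
        st = deck.strategy("TURP")
        for ae in st.ae_profiles:
            if ae.category == "periprocedural":
                ae.rate_schedule = ae.rate_schedule + ((1.0, 0.05),)
                break
        v = validate_deck(deck)
        assert any("index cycle" in x.rule for x in v)


class TestLoadSaveRoundTrip:
    def test_packaged_deck_equals_programmatic_build(self):
        assert load_input_deck(reference_deck_path()) == build_reference_deck()

    def test_save_then_load_is_identity(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        again = load_input_deck(tmp_path / "d")
        assert again == ref_deck

    def test_round_trip_preserves_full_float_precision(self, deck, tmp_path):
        deck.strategy("PUL").retreatment.rate_schedule = (
            (0.0, 0.009124116404740534), (1.0, 0.08),
        )
        save_deck(deck, tmp_path / "d")
        again = load_input_deck(tmp_path / "d")
        assert again.strategy("PUL").retreatment.rate_schedule \
            == deck.strategy("PUL").retreatment.rate_schedule

    def test_directory_or_manifest_path_both_work(self, ref_deck, tmp_path):
        mpath = save_deck(ref_deck, tmp_path / "d")
        assert load_input_deck(mpath) == load_input_deck(tmp_path / "d")


class TestLoadRejections:
    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_input_deck(tmp_path / "nope")

    def test_missing_table(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        (tmp_path / "d" / "life_table.csv").unlink()
        with pytest.raises(FileNotFoundError):
            load_input_deck(tmp_path / "d")

    def _edit_manifest(self, tmp_path, mutate):
        with open(tmp_path / "d" / "deck.yaml") as fh:
            m = yaml.safe_load(fh)
        mutate(m)
        with open(tmp_path / "d" / "deck.yaml", "w") as fh:
            yaml.safe_dump(m, fh)

    def test_unknown_manifest_key(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        self._edit_manifest(tmp_path, lambda m: m.update(surprise=1))
        with pytest.raises(DeckError, match="unknown manifest keys"):
            load_input_deck(tmp_path / "d")

    def test_unknown_settings_key(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        self._edit_manifest(tmp_path, lambda m: m["settings"].update(bogus=2))
        with pytest.raises(DeckError, match="unknown settings keys"):
            load_input_deck(tmp_path / "d")

    def test_unknown_table_key(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        self._edit_manifest(tmp_path, lambda m: m["tables"].update(extra="x.csv"))
        with pytest.raises(DeckError, match="unknown table keys"):
            load_input_deck(tmp_path / "d")

    def test_unknown_cost_kind(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        with open(tmp_path / "d" / "costs.csv", "a") as fh:
            fh.write("thing,mystery_kind,1.0\n")
        with pytest.raises(DeckError, match="unknown kind"):
            load_input_deck(tmp_path / "d")

    def test_missing_column(self, ref_deck, tmp_path):
        save_deck(ref_deck, tmp_path / "d")
        df = pd.read_csv(tmp_path / "d" / "life_table.csv")
        df.drop(columns=["qx"]).to_csv(tmp_path / "d" / "life_table.csv", index=False)
        with pytest.raises(DeckError, match="missing columns"):
            load_input_deck(tmp_path / "d")

    def test_invalid_deck_rejected_on_load(self, deck, tmp_path):
        deck.utilities.utility_by_severity["mild"] = 1.5
        save_deck(deck, tmp_path / "d")
        with pytest.raises(DeckError, match="validation failed"):
            load_input_deck(tmp_path / "d")


class TestPackagedDeckValues:
    """Spot-check the shipped reference deck against its documented inputs."""

    def test_procedure_costs(self, ref_deck):
        expected = {"PUL": 7258.0, "WVTT": 1867.0, "PVP": 4813.0, "TURP": 5157.0}
        for name, cost in expected.items():
            assert ref_deck.strategy(name).procedure_cost == cost
        assert ref_deck.strategy("CT").procedure_cost == 0.0
        assert ref_deck.strategy("CT").drug_cost_per_day == 3.73

    def test_catheterization_rates(self, ref_deck):
        expected = {"PUL": 0.514, "WVTT": 0.904, "PVP": 0.941, "TURP": 0.932}
        for name, rate in expected.items():
            assert ref_deck.strategy(name).catheterization_rate == rate

    def test_visit_and_followup_costs(self, ref_deck):
        assert ref_deck.costs.office_visit == 87.0
        assert ref_deck.costs.followup_by_severity == {
            "mild": 87.0, "moderate": 97.0, "severe": 184.0}
        assert ref_deck.costs.medical_therapy_annual == 105.0

    def test_settings(self, ref_deck):
        s = ref_deck.settings
        assert s.discount_rate_annual == 0.03
        assert s.wtp_threshold == 50_000.0
        assert s.horizon_years == 5.0
        assert s.cycle_plan == (0.25, 0.25, 0.25, 0.25, 1.0, 1.0, 1.0, 1.0)
        assert s.reference_strategy == "CT"
        assert ref_deck.cohort.start_age == 63.0
        assert ref_deck.cohort.baseline_ipss_mean == 22.0
        assert ref_deck.cohort.baseline_ipss_sd == 4.8


class TestExportResults:
    @staticmethod
    def _result():
        totals = [StrategyTotals("A", 8222.7, 4.1183),
                  StrategyTotals("B", 6151.6, 4.2459)]
        return incremental_analysis(totals, reference="A", wtp_threshold=50_000.0)

    def test_csv_has_raw_and_display_columns(self, tmp_path):
        path = export_results(self._result(), tmp_path / "out.csv")
        df = pd.read_csv(path, dtype={"total_cost_display": str,
                                      "total_qalys_display": str})
        row = df[df["strategy"] == "B"].iloc[0]
        assert row["total_cost"] == 6151.6  # unrounded value persisted
        assert row["total_cost_display"] == "6152"
        assert row["total_qalys_display"] == "4.246"
        assert row["label"] == "dominates"

    def test_json_format(self, tmp_path):
        path = export_results(self._result(), tmp_path / "out.json", format="json")
        records = json.loads(path.read_text())
        assert {r["strategy"] for r in records} == {"A", "B"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_results(self._result(), tmp_path / "x.bin", format="bin")

    def test_unexportable_object_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            export_results(object(), tmp_path / "x.csv")
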