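"""Parameter registry, OWSA, PSA, scenario rerun, and calibration."""

from __future__ import annotations

import logging

import pandas as pd
import pytest

from bphcea.engine import run_cohort
from bphcea.uncertainty import (
    CalibrationParameter,
    ParameterSpec,
    UncertaintySettings,
    build_default_registry,
    calibrate_open_parameters,
    default_open_parameters,
    get_param,
    run_owsa,
    run_psa,
    run_scenario,
    set_param,
)


class TestParameterPaths:
    def test_attribute_leaf(self, deck):
        assert get_param(deck, "strategies[WVTT].procedure_cost") == 1867.0
        set_param(deck, "strategies[WVTT].procedure_cost", 2000.0)
        assert deck.strategy("WVTT").procedure_cost == 2000.0

    def test_dict_leaf(self, deck):
        path = "utilities.utility_by_severity[severe]"
        base = get_param(deck, path)
        set_param(deck, path, base - 0.05)
        assert deck.utilities.utility_by_severity["severe"] == base - 0.05

    def test_tuple_index_leaf(self, deck):
        path = "trajectories[WVTT].means[3]"
        base = get_param(deck, path)
        set_param(deck, path, base + 1.0)
        assert deck.trajectories["WVTT"].means[3] == base + 1.0

    def test_settings_leaf(self, deck):
        set_param(deck, "settings.discount_rate_annual", 0.05)
        assert deck.settings.discount_rate_annual == 0.05

    def test_rate_scale_pseudo_leaf(self, deck):
        path = "strategies[PUL].retreatment.rate_scale"
        assert get_param(deck, path) == 1.0
        before = deck.strategy("PUL").retreatment.rate_schedule
        set_param(deck, path, 2.0)
        after = deck.strategy("PUL").retreatment.rate_schedule
        assert [t for t, _ in after] == [t for t, _ in before]
        for (_, r0), (_, r1) in zip(before, after):
            assert r1 == pytest.approx(min(2.0 * r0, 1.0))

    def test_default_registry_paths_resolve(self, ref_deck):
        for spec in build_default_registry(ref_deck):
            val = get_param(ref_deck, spec.path)
            assert spec.lo <= val <= spec.hi


class TestOWSA:
    def test_matches_scripted_rerun(self, ref_deck):
        """Single-parameter tornado versus a hand-scripted perturb-and-rerun."""
        spec = ParameterSpec("WVTT Treatment Cost",
                             "strategies[WVTT].procedure_cost", lo=0.0)
        settings = UncertaintySettings(registry=[spec], metric="icer")
        [entry] = run_owsa(ref_deck, ("WVTT", "CT"), settings)

        outcomes = []
        for mult in (0.9, 1.1):
            d = ref_deck.copy()
            d.strategy("WVTT").procedure_cost = 1867.0 * mult
            a, b = run_cohort(d, "WVTT"), run_cohort(d, "CT")
            outcomes.append((a.total_cost - b.total_cost)
                            / (a.total_qalys - b.total_qalys))
        assert entry.outcome_low == pytest.approx(outcomes[0], rel=1e-12)
        assert entry.outcome_high == pytest.approx(outcomes[1], rel=1e-12)

    def test_cost_parameter_spread_is_linear_in_fraction(self, ref_deck):
        spec = ParameterSpec("WVTT Treatment Cost",
                             "strategies[WVTT].procedure_cost", lo=0.0)
        s1 = UncertaintySettings(registry=[spec], owsa_fraction=0.10)
        s2 = UncertaintySettings(registry=[spec], owsa_fraction=0.20)
        [e1] = run_owsa(ref_deck, ("WVTT", "CT"), s1)
        [e2] = run_owsa(ref_deck, ("WVTT", "CT"), s2)
        assert e2.spread == pytest.approx(2.0 * e1.spread, rel=1e-9)

    def test_entries_ranked_by_spread_and_capped(self, ref_deck):
        entries = run_owsa(ref_deck, ("WVTT", "CT"),
                           UncertaintySettings(metric="nmb"), top=10)
        assert len(entries) == 10
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_out_of_range_perturbation_clamped_with_warning(self, ref_deck, caplog):
        # PVP catheterization is 0.941; +10% would exceed 1.0
        spec = ParameterSpec("PVP Catheterization Rate",
                             "strategies[PVP].catheterization_rate",
                             lo=0.0, hi=1.0)
        with caplog.at_level(logging.WARNING, logger="bphcea.uncertainty"):
            [entry] = run_owsa(ref_deck, ("PVP", "CT"),
                               UncertaintySettings(registry=[spec]))
        assert "clamped" in caplog.text
        d = ref_deck.copy()
        d.strategy("PVP").catheterization_rate = 1.0
        a, b = run_cohort(d, "PVP"), run_cohort(d, "CT")
        want = (a.total_cost - b.total_cost) / (a.total_qalys - b.total_qalys)
        assert entry.outcome_high == pytest.approx(want, rel=1e-12)


class TestPSA:
    @staticmethod
    def _small_registry():
        return [
            ParameterSpec("WVTT Treatment Cost",
                          "strategies[WVTT].procedure_cost", lo=0.0),
            ParameterSpec("CT Treatment Cost",
                          "strategies[CT].drug_cost_per_day", lo=0.0),
            ParameterSpec("Severe BPH Utility",
                          "utilities.utility_by_severity[severe]", lo=0.0, hi=1.0),
        ]

    def test_zero_width_sampling_reproduces_base_exactly(self, ref_deck):
        registry = [ParameterSpec("WVTT Treatment Cost",
                                  "strategies[WVTT].procedure_cost",
                                  sd=0.0, lo=0.0)]
        res = run_psa(ref_deck, UncertaintySettings(psa_draws=5, registry=registry))
        for p in res.points:
            for name, (cost, qaly) in res.base.items():
                assert p.costs[name] == cost
                assert p.qalys[name] == qaly

    def test_same_seed_bit_reproducible(self, ref_deck):
        s = UncertaintySettings(psa_draws=20, rng_seed=7,
                                registry=self._small_registry())
        a = run_psa(ref_deck, s)
        b = run_psa(ref_deck, s)
        assert a.to_frame().equals(b.to_frame())

    def test_different_seeds_differ(self, ref_deck):
        reg = self._small_registry()
        a = run_psa(ref_deck, UncertaintySettings(psa_draws=10, rng_seed=1,
                                                  registry=reg))
        b = run_psa(ref_deck, UncertaintySettings(psa_draws=10, rng_seed=2,
                                                  registry=reg))
        assert not a.to_frame().equals(b.to_frame())

    def test_draws_stay_within_documented_interval(self, ref_deck):
        reg = [ParameterSpec("WVTT Treatment Cost",
                             "strategies[WVTT].procedure_cost", lo=0.0)]
        res = run_psa(ref_deck, UncertaintySettings(psa_draws=40, rng_seed=3,
                                                    registry=reg))
        # cost varies only through the WVTT procedure line, so the draw-level
        # totals stay inside +/-10% of the base procedure cost around base
        base_cost = res.base["WVTT"][0]
        for p in res.points:
            assert abs(p.costs["WVTT"] - base_cost) <= 0.10 * 1867.0 + 1e-9
            assert p.qalys["WVTT"] == res.base["WVTT"][1]

    def test_quadrant_fractions_well_formed(self, ref_deck):
        res = run_psa(ref_deck, UncertaintySettings(psa_draws=15, rng_seed=11,
                                                    registry=self._small_registry()))
        q = res.quadrant_fractions()
        assert set(q) == {"PUL", "WVTT", "PVP", "TURP"}
        for frac in q.values():
            assert 0.0 <= frac["cheaper"] <= 1.0
            assert 0.0 <= frac["more_effective"] <= 1.0


class TestScenario:
    @staticmethod
    def _trajectory_frame(deck, names=None):
        rows = []
        for name in (names or deck.trajectories):
            tr = deck.trajectories[name]
            for t, m, s in zip(tr.times, tr.means, tr.sds):
                rows.append({"strategy": name, "time_years": t,
                             "ipss_mean": m, "ipss_sd": s})
        return pd.DataFrame(rows)

    def test_identity_scenario_reproduces_base(self, ref_deck):
        res = run_scenario(ref_deck, self._trajectory_frame(ref_deck))
        for name in ref_deck.strategy_names():
            tr = run_cohort(ref_deck, name)
            row = res.row(name)
            assert row.cost == tr.total_cost
            assert row.qalys == tr.total_qalys

    def test_untouched_strategies_bit_identical(self, ref_deck):
        frame = self._trajectory_frame(ref_deck, ["CT"])
        frame.loc[frame["time_years"] > 0, "ipss_mean"] += 2.0
        res = run_scenario(ref_deck, frame)
        wvtt = run_cohort(ref_deck, "WVTT")
        assert res.row("WVTT").cost == wvtt.total_cost
        assert res.row("WVTT").qalys == wvtt.total_qalys
        # the modified strategy did change
        assert res.row("CT").qalys != run_cohort(ref_deck, "CT").total_qalys

    def test_schema_violation_rejected(self, ref_deck):
        bad = self._trajectory_frame(ref_deck).drop(columns=["ipss_sd"])
        with pytest.raises(ValueError, match="missing columns"):
            run_scenario(ref_deck, bad)


class TestCalibration:
    def test_empty_free_list_is_identity(self, ref_deck):
        targets = {"WVTT": (2655.0, 4.189)}
        fitted, values, residuals = calibrate_open_parameters(
            ref_deck, targets, free=[])
        assert fitted == ref_deck
        assert values == {}
        tr = run_cohort(ref_deck, "WVTT")
        assert residuals["WVTT"][0] == pytest.approx(
            (tr.total_cost - 2655.0) / 2655.0)

    def test_default_open_parameters_cover_documented_set(self, ref_deck):
        names = {p.name for p in default_open_parameters(ref_deck)}
        assert "ct_mist_pul_share" in names
        assert "post_year1_retreat_scale" in names
        assert "severity_cutoff_shift" in names
        assert {"repeat_share_PUL", "repeat_share_WVTT",
                "repeat_share_PVP", "repeat_share_TURP"} <= names

    def test_recovers_self_consistent_targets(self, ref_deck):
        """Targets generated by the model itself are fit to near-zero residual."""
        params = {p.name: p for p in default_open_parameters(ref_deck)}
        free = [params["repeat_share_PUL"], params["post_year1_retreat_scale"]]
        truth = ref_deck.copy()
        free[0].apply(truth, 0.4)
        free[1].apply(truth, 1.5)
        targets = {}
        for name in ("PUL", "WVTT"):
            tr = run_cohort(truth, name)
            targets[name] = (tr.total_cost, tr.total_qalys)

        fitted, values, residuals = calibrate_open_parameters(
            ref_deck, targets, free=free, maxiter=2000)
        for rc, rq in residuals.values():
            assert abs(rc) < 1e-4
            assert abs(rq) < 1e-4
        assert values["repeat_share_PUL"] == pytest.approx(0.4, abs=0.02)

    def test_bounds_respected(self, ref_deck):
        params = {p.name: p for p in default_open_parameters(ref_deck)}
        free = [params["repeat_share_WVTT"]]
        # an absurdly high cost target pushes the share toward its upper bound
        targets = {"WVTT": (50_000.0, 4.189)}
        _, values, _ = calibrate_open_parameters(ref_deck, targets, free=free,
                                                 maxiter=100)
        assert 0.0 <= values["repeat_share_WVTT"] <= 1.0
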