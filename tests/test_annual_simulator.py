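"""Orchestration: step order, ledger bookkeeping, mass balance, determinism."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from cbmcn.annual_simulator import (
    FluxLedger,
    RunConfig,
    check_mass_balance,
    run_prepared,
)
from cbmcn.biomass_growth import GrowthCurve
from cbmcn.model_core import (
    ClimateSeries,
    DisturbanceEvent,
    POOLS,
    StandRecord,
)
from cbmcn.synthetic_fixtures import generate_parameters


CFG = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2016)


def _mini_setup(params_seed=3):
    """One softwood stand with simple, hand-checkable parameters."""
    p = copy.deepcopy(generate_parameters(params_seed))
    stand = StandRecord(
        stand_id="M1", spu_id="1", species="chinese_fir", genus_class="softwood",
        forest_type="arbour", origin="planted", land_use="forest", age=5, area=1.0,
        climatic_zone="mid_subtropical", site_quality="2", rocky_desertification="none",
    )
    key = stand.classifier_key
    # tabulated curve: volume = 10 * age up to age 50
    p.growth_curves[key] = GrowthCurve(key, "tabulated", (50.0, 500.0), max_age=50)
    # flat quarters allocation, stem biomass = 0.4 V
    am = p.allocation_models["chinese_fir"]
    p.allocation_models["chinese_fir"] = type(am)(
        species="chinese_fir", stem_a=0.4, stem_b=1.0,
        logit={k: (0.0, 0.0) for k in ("stemwood", "bark", "branches", "foliage")},
    )
    for comp in POOLS[:5]:
        p.c_content[("chinese_fir", comp)] = 0.5
    climate = {"1": ClimateSeries("1", {y: 15.0 for y in range(1990, 2017)}, historic_mean=15.0)}
    return stand, p, climate


class TestThreeYearHandTrajectory:
    def test_matches_plain_float_oracle(self):
        """A 1-stand, 3-year run against an independent plain-Python recompute
        of the documented annual recipe (growth -> turnover/snag fall ->
        decay/mixing), starting from empty DOM pools."""
        stand, p, climate = _mini_setup()
        # start from zero DOM: replace spin-up with a fresh stand at age 0 by
        # running the simulator on a stand whose spin-up is neutralised
        from cbmcn import annual_simulator as sim

        p2 = copy.deepcopy(p)
        # direct state construction (empty DOM) instead of spin-up
        state = sim.SimulationState(year=1990)
        state.stands[stand.stand_id] = stand
        from cbmcn.model_core import PoolVector

        state.pools[stand.stand_id] = PoolVector.zeros()
        state.transitions[stand.stand_id] = None
        ledger = FluxLedger()
        frames = [sim.snapshot(state)]
        for _ in range(3):
            state = sim.step_year(state, p2, climate, {}, ledger)
            frames.append(sim.snapshot(state))
        annual = pd.concat(frames, ignore_index=True)

        # ---- independent oracle in plain floats ----------------------------
        rates = [p.turnover.rates[("coniferous", c)] for c in POOLS[:5]]
        s_stem, s_branch = p.snag_fall["softwood"]
        merch_frac = p.merch_proportion["chinese_fir"]
        k = p.decay.applied_rates(15.0)
        p_atm = p.decay.p_atm
        root_a = 0.222
        fine_a, fine_b, fine_k = 0.072, 0.354, 0.06

        def live_at(age):
            vol = 10.0 * age
            if vol == 0.0:
                return [0.0] * 5
            b_stem = 0.4 * vol
            agb = 4.0 * b_stem          # equal quarters
            stem_bark = 0.5 * agb       # stemwood + bark quarters
            branches = 0.25 * agb
            fol = 0.25 * agb
            roots = root_a * agb
            fine = roots * (fine_a + fine_b * math.exp(-fine_k * roots))
            coarse = roots - fine
            group_thresholds = p.age_groups["chinese_fir"]
            group_i = sum(age >= t for t in group_thresholds)
            if group_i >= 3:  # MF or PMF
                merch, other = merch_frac * stem_bark, (1 - merch_frac) * stem_bark + branches
            else:
                merch, other = 0.0, stem_bark + branches
            return [x * 0.5 for x in (merch, other, fol, coarse, fine)]  # C content

        pools = {name: 0.0 for name in POOLS}
        age = 5
        for _ in range(3):
            now, nxt = live_at(age), live_at(age + 1)
            for i, name in enumerate(POOLS[:5]):
                pools[name] += max(nxt[i] - now[i], 0.0)
            age += 1
            # turnover
            moved = [pools[name] * rates[i] for i, name in enumerate(POOLS[:5])]
            for i, name in enumerate(POOLS[:5]):
                pools[name] -= moved[i]
            pools["snag_stem"] += moved[0]
            pools["snag_branch"] += moved[1]
            pools["ag_very_fast"] += moved[2] + 0.5 * moved[4]
            pools["bg_very_fast"] += 0.5 * moved[4]
            pools["ag_fast"] += 0.5 * moved[3]
            pools["bg_fast"] += 0.5 * moved[3]
            fall_s, fall_b = pools["snag_stem"] * s_stem, pools["snag_branch"] * s_branch
            pools["snag_stem"] -= fall_s
            pools["medium"] += fall_s
            pools["snag_branch"] -= fall_b
            pools["ag_fast"] += fall_b
            # decay
            dom_names = POOLS[5:]
            decayed = {n: pools[n] * k[j] for j, n in enumerate(dom_names)}
            ag_res = bg_res = 0.0
            for j, n in enumerate(dom_names):
                if n in ("ag_slow", "bg_slow"):
                    pools[n] -= decayed[n] * p_atm[j]
                else:
                    pools[n] -= decayed[n]
                    res = decayed[n] * (1 - p_atm[j])
                    if n.startswith("bg"):
                        bg_res += res
                    else:
                        ag_res += res
            pools["ag_slow"] += ag_res
            pools["bg_slow"] += bg_res
            mixed = pools["ag_slow"] * p.decay.slow_mixing_rate
            pools["ag_slow"] -= mixed
            pools["bg_slow"] += mixed

        final = annual[annual.year == 1993].iloc[0]
        for name in POOLS:
            assert final[name] == pytest.approx(pools[name], rel=1e-12, abs=1e-12), name


class TestEventBookkeeping:
    def test_single_harvest_event_recorded_once_and_age_reset(self):
        stand, p, climate = _mini_setup()
        stand = stand.with_(age=40)  # beyond harvest age 25
        events = [DisturbanceEvent(1995, "M1", "HL", post_land_use="forest")]
        cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2000)
        annual, ledger = run_prepared([stand], p, climate, events, cfg)
        edf = ledger.events_dataframe()
        assert len(edf) == 1
        assert edf.iloc[0]["dtype"] == "HL" and edf.iloc[0]["year"] == 1995
        # one coherent disturbance record group, one gas record
        ldf = ledger.to_dataframe()
        dist = ldf[ldf.process == "disturbance:HL"]
        assert not dist.empty and set(dist.year) == {1995}
        assert len(ledger.gases) == 1
        # age reset to 1 at the event year -> age 6 in 2000
        # (snapshot ages are not exported; verify via regrown live carbon)
        assert annual[annual.year == 1996][list(POOLS[:5])].sum(axis=1).iloc[0] < \
               annual[annual.year == 1994][list(POOLS[:5])].sum(axis=1).iloc[0]

    def test_event_on_unknown_stand_is_an_error(self):
        stand, p, climate = _mini_setup()
        events = [DisturbanceEvent(1995, "GHOST", "HL")]
        cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2000)
        with pytest.raises(KeyError, match="GHOST"):
            run_prepared([stand], p, climate, events, cfg)

    def test_missing_climate_year_is_an_error(self):
        stand, p, _ = _mini_setup()
        climate = {"1": ClimateSeries("1", {1990: 15.0, 1991: 15.0}, historic_mean=15.0)}
        cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2000)
        with pytest.raises(KeyError, match="1992"):
            run_prepared([stand], p, climate, [], cfg)


class TestMassBalanceAndDeterminism:
    def test_small_run_mass_balance_closes(self, small_run):
        residual = check_mass_balance(small_run["ledger"], small_run["annual"])
        assert residual < 1e-9

    def test_mutated_ledger_is_flagged(self, small_run):
        ledger = small_run["ledger"]
        broken = FluxLedger()
        big = max(range(len(ledger.records)), key=lambda i: ledger.records[i][5])
        broken.records = [r for i, r in enumerate(ledger.records) if i != big]
        assert check_mass_balance(broken, small_run["annual"]) > 1e-9

    def test_empty_simulation_has_zero_residual(self):
        assert check_mass_balance(FluxLedger(), pd.DataFrame()) == 0.0

    def test_rerun_is_bit_identical(self, small_run):
        annual2, _ = run_prepared(
            small_run["stands"], small_run["params"], small_run["climate"],
            small_run["events"], small_run["config"],
        )
        pd.testing.assert_frame_equal(small_run["annual"], annual2)

    def test_stand_order_permutation_invariance(self, small_run):
        stands = list(small_run["stands"])
        rng = np.random.default_rng(5)
        perm = [stands[i] for i in rng.permutation(len(stands))]
        annual2, _ = run_prepared(
            perm, small_run["params"], small_run["climate"],
            small_run["events"], small_run["config"],
        )
        a = small_run["annual"].sort_values(["year", "stand_id"]).reset_index(drop=True)
        b = annual2.sort_values(["year", "stand_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_stand_independence(self, small_run):
        """Simulating two stands separately equals the joint run."""
        stands = [s for s in small_run["stands"] if s.is_forest][:2]
        p, climate = small_run["params"], small_run["climate"]
        events = [e for e in small_run["events"] if e.stand_id in {s.stand_id for s in stands}]
        joint, _ = run_prepared(stands, p, climate, events, small_run["config"])
        parts = []
        for s in stands:
            ev = [e for e in events if e.stand_id == s.stand_id]
            single, _ = run_prepared([s], p, climate, ev, small_run["config"])
            parts.append(single)
        merged = pd.concat(parts, ignore_index=True).sort_values(
            ["year", "stand_id"]).reset_index(drop=True)
        joint = joint.sort_values(["year", "stand_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(joint, merged)

    def test_27_annual_states_for_1990_2016(self, small_run):
        assert small_run["annual"]["year"].nunique() == 27


class TestNonForestDynamics:
    def test_deforestation_starts_soil_transition_toward_class_default(self):
        stand, p, climate = _mini_setup()
        stand = stand.with_(age=20)
        events = [DisturbanceEvent(1995, "M1", "DFA", post_land_use="cropland_dryland")]
        cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2016)
        annual, ledger = run_prepared([stand], p, climate, events, cfg)
        target = p.soil_defaults["dryland"] * stand.area
        bg = annual.set_index("year")["bg_slow"]
        assert bg.loc[2016] == pytest.approx(target, rel=1e-9)
        # transition completes exactly at the 20-year mark and then holds
        assert bg.loc[2015] == pytest.approx(target, rel=1e-9)
        assert bg.loc[2014] != pytest.approx(target, rel=1e-6)
        assert check_mass_balance(ledger, annual) < 1e-9
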