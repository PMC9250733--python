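"""Annual-timestep orchestration over all stands and years, with a full flux
ledger and mass-balance auditing.

Each simulated year runs, for every forested stand: (1) net growth increment
and age increment, (2) biomass turnover and snag fall, (3) temperature-
dependent DOM decay and slow mixing at the stand's spatial-unit temperature,
(4) any scheduled disturbance (matrix application, gas speciation, stand
reset).  Non-forest stands only update their 20-year belowground-slow
transition.  Every transfer is recorded, so for each stand-year the identity

    pools(t+1) - pools(t) = uptake - atmosphere flux - products flux

can be audited exactly.  Stands are independent: the joint run equals the
union of single-stand runs, and stand order never changes a result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_core as mc
from .biomass_growth import clear_trajectory_cache, live_carbon_trajectory
from .disturbance_engine import (
    apply_disturbance,
    post_disturbance_reset,
    speciate_emissions,
)
from .dom_dynamics import apply_turnover, decay_step, routing_matrix
from .initialisation import nonforest_bgslow, spinup_stand
from .model_core import (
    I_ATM,
    I_BG_SLOW,
    I_PRODUCTS,
    LAND_USE_TO_SOIL_CLASS,
    N_LIVE,
    N_POOLS,
    POOLS,
    SLOTS,
    LookupFailure,
    ParameterSet,
    PoolVector,
    StandRecord,
)


class FluxLedger:
    """Every carbon transfer of a run, keyed (year, stand, process, source, target).

    ``process`` is one of growth, turnover, decay, mixing, soil_transition or
    disturbance:<dtype>.  Flows from 'atmosphere' are uptake; flows to
    'atmosphere' / 'products' are expenditures.  Disturbance events also log
    per-event gas masses and disturbed area.
    """

    def __init__(self):
        self.records: list[tuple] = []
        self.gases: list[dict] = []
        self.events_applied: list[dict] = []

    def add(self, year, stand_id, process, source, target, amount) -> None:
        if amount != 0.0:
            self.records.append((year, stand_id, process, source, target, float(amount)))

    def add_event(self, year, stand_id, dtype, area, gases) -> None:
        self.events_applied.append(
            {"year": year, "stand_id": stand_id, "dtype": dtype, "area_ha": area}
        )
        self.gases.append(
            {"year": year, "stand_id": stand_id, "dtype": dtype, "area_ha": area, **gases}
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["year", "stand_id", "process", "source", "target", "mg_c"]
        )

    def gases_dataframe(self) -> pd.DataFrame:
        cols = ["year", "stand_id", "dtype", "area_ha", "co2", "co", "ch4", "n2o"]
        if not self.gases:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.gases)[cols]

    def events_dataframe(self) -> pd.DataFrame:
        cols = ["year", "stand_id", "dtype", "area_ha"]
        if not self.events_applied:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.events_applied)[cols]

    def merge(self, other: "FluxLedger") -> "FluxLedger":
        out = FluxLedger()
        out.records = self.records + other.records
        out.gases = self.gases + other.gases
        out.events_applied = self.events_applied + other.events_applied
        return out


@dataclass
class SoilTransition:
    """In-progress 20-year belowground-slow adjustment of a non-forest stand."""

    start_year: int
    start_mg: float      # whole-stand Mg C at conversion
    target_mg: float

    def value(self, year: int, transition_years: int) -> float:
        t = min(max(year - self.start_year, 0), transition_years)
        return self.start_mg + (self.target_mg - self.start_mg) * t / transition_years


@dataclass
class SimulationState:
    year: int
    stands: dict = field(default_factory=dict)        # stand_id -> StandRecord
    pools: dict = field(default_factory=dict)         # stand_id -> PoolVector
    transitions: dict = field(default_factory=dict)   # stand_id -> SoilTransition | None
    spinup_converged: dict = field(default_factory=dict)

    def total_carbon(self) -> float:
        return sum(pv.total_pools() for pv in self.pools.values())


def _soil_class(land_use: str) -> str:
    try:
        return LAND_USE_TO_SOIL_CLASS[land_use]
    except KeyError:
        raise LookupFailure(f"no soil class for land use {land_use!r}") from None


def initialise_state(
    stands: list, p: ParameterSet, climate: dict, start_year: int
) -> SimulationState:
    """Spin up forest stands and seed non-forest stands with soil defaults."""
    state = SimulationState(year=start_year)
    for s in stands:
        if s.stand_id in state.stands:
            raise mc.ValidationError(f"duplicate stand_id {s.stand_id!r}")
        state.stands[s.stand_id] = s
        if s.is_forest:
            cfg = p.spinup.get(s.spu_id) or p.spinup.get("default")
            if cfg is None:
                raise LookupFailure(f"no spin-up config for SPU {s.spu_id!r}")
            historic = climate[s.spu_id].historic()
            result = spinup_stand(s, p, cfg, historic)
            state.pools[s.stand_id] = result.pools
            state.spinup_converged[s.stand_id] = result.converged
            state.transitions[s.stand_id] = None
        else:
            pv = PoolVector.zeros()
            pv.data[I_BG_SLOW] = p.soil_defaults[_soil_class(s.land_use)] * s.area
            state.pools[s.stand_id] = pv
            state.transitions[s.stand_id] = None
    return state


def step_year(
    state: SimulationState,
    p: ParameterSet,
    climate: dict,
    events_by_year: dict,
    ledger: FluxLedger,
    disturbance_first: bool = False,
) -> SimulationState:
    """Advance the state by one year (in place) and return it."""
    year = state.year + 1
    events = {e.stand_id: e for e in events_by_year.get(year, ())}
    for sid in events:
        if sid not in state.stands:
            raise LookupFailure(f"event in {year} references unknown stand {sid!r}")
    routing = routing_matrix()

    for sid, stand in state.stands.items():
        if disturbance_first:
            stand = _apply_event(state, sid, stand, events, p, year, ledger)
        if stand.is_forest:
            temperature = climate[stand.spu_id].temperature(year)
            pools = state.pools[sid]

            # (1) growth + age increment
            traj = live_carbon_trajectory(stand, p, stand.age + 1)
            a0 = min(stand.age, traj.shape[0] - 1)
            a1 = min(stand.age + 1, traj.shape[0] - 1)
            delta = np.maximum(traj[a1] - traj[a0], 0.0) * stand.area
            pools.data[:N_LIVE] += delta
            for i in range(N_LIVE):
                ledger.add(year, sid, "growth", "atmosphere", POOLS[i], delta[i])
            stand = stand.with_(age=stand.age + 1)

            # (2) turnover + snag fall
            rec: list = []
            pools = apply_turnover(
                pools,
                p.turnover,
                p.snag_fall[stand.genus_class],
                tclass=p.turnover_class(stand),
                routing=routing,
                record=rec,
            )
            for source, target, amount in rec:
                ledger.add(year, sid, "turnover", source, target, amount)

            # (3) decay + mixing
            rec = []
            pools, _ = decay_step(pools, p.decay, temperature, record=rec)
            for source, target, amount in rec:
                process = "mixing" if (source, target) == ("ag_slow", "bg_slow") else "decay"
                ledger.add(year, sid, process, source, target, amount)

            state.pools[sid] = pools
        else:
            # non-forest stands only track the belowground-slow transition
            tr = state.transitions.get(sid)
            if tr is not None:
                pools = state.pools[sid]
                new_val = tr.value(year, p.transition_years)
                diff = new_val - pools.data[I_BG_SLOW]
                if diff > 0:
                    pools.data[I_BG_SLOW] = new_val
                    ledger.add(year, sid, "soil_transition", "atmosphere", "bg_slow", diff)
                elif diff < 0:
                    pools.data[I_BG_SLOW] = new_val
                    pools.data[I_ATM] += -diff
                    ledger.add(year, sid, "soil_transition", "bg_slow", "atmosphere", -diff)
                if year - tr.start_year >= p.transition_years:
                    state.transitions[sid] = None

        if not disturbance_first:
            stand = _apply_event(state, sid, stand, events, p, year, ledger)
        state.stands[sid] = stand

    state.year = year
    return state


def _apply_event(state, sid, stand, events, p: ParameterSet, year, ledger: FluxLedger) -> StandRecord:
    event = events.get(sid)
    if event is None:
        return stand
    dtype = event.dtype
    try:
        matrix = p.matrices[dtype]
    except KeyError:
        raise LookupFailure(f"no disturbance matrix for {dtype!r}") from None
    rec: list = []
    pools, to_atm, to_products, burned = apply_disturbance(state.pools[sid], matrix, record=rec)
    process = f"disturbance:{dtype}"
    for source, target, amount in rec:
        ledger.add(year, sid, process, source, target, amount)
    gases = speciate_emissions(burned, max(to_atm - burned, 0.0), p.emission_factors)
    ledger.add_event(year, sid, dtype, stand.area, gases)
    state.pools[sid] = pools

    was_forest = stand.is_forest
    new_stand = post_disturbance_reset(stand, dtype, event)
    if was_forest and not new_stand.is_forest:
        # start the 20-year soil adjustment toward the new class default
        target = p.soil_defaults[_soil_class(new_stand.land_use)] * new_stand.area
        state.transitions[sid] = SoilTransition(
            start_year=year, start_mg=float(pools.data[I_BG_SLOW]), target_mg=target
        )
    elif not was_forest and new_stand.is_forest:
        # afforestation freezes the non-forest transition; forest dynamics take over
        state.transitions[sid] = None
    return new_stand


@dataclass
class RunConfig:
    """Run manifest: input paths, simulated period, behaviour flags."""

    parameters: str
    inventory: str
    climate: str
    events: str | None = None
    start_year: int = 1990
    end_year: int = 2016
    strict: bool = True
    disturbance_first: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("parameters", "inventory", "climate", "events"):
            if raw.get(key):
                raw[key] = str((base / raw[key]).resolve())
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})


def snapshot(state: SimulationState) -> pd.DataFrame:
    rows = []
    for sid, stand in state.stands.items():
        pv = state.pools[sid]
        row = {"year": state.year, "stand_id": sid, "land_use": stand.land_use, "area_ha": stand.area}
        row.update({name: pv.data[i] for i, name in enumerate(SLOTS)})
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig | str, out_dir=None) -> tuple:
    """Run a full simulation; returns (annual pool table, flux ledger).

    The annual table holds one row per stand per year (start year plus each
    simulated year: a start of 1990 and end of 2016 yields 27 annual states).
    Deterministic: identical configs give bit-identical outputs.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    p = mc.load_parameters(config.parameters, strict=config.strict)
    stands = mc.load_inventory(config.inventory)
    climate = mc.load_climate(config.climate)
    events = mc.load_events(config.events) if config.events else []
    violations = mc.validate_parameter_set(p, stands)
    if violations:
        raise mc.ValidationError("; ".join(violations))
    return run_prepared(stands, p, climate, events, config, out_dir)


def run_prepared(stands, p, climate, events, config: RunConfig, out_dir=None) -> tuple:
    """Like :func:`run` but with already-loaded inputs."""
    clear_trajectory_cache()
    events_by_year: dict = {}
    for e in events:
        events_by_year.setdefault(e.year, []).append(e)

    state = initialise_state(stands, p, climate, config.start_year)
    ledger = FluxLedger()
    frames = [snapshot(state)]
    for _ in range(config.start_year, config.end_year):
        state = step_year(
            state, p, climate, events_by_year, ledger, config.disturbance_first
        )
        frames.append(snapshot(state))
    annual = pd.concat(frames, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annual.to_csv(out / "annual_pools.csv", index=False)
        ledger.to_dataframe().to_csv(out / "ledger.csv", index=False)
        ledger.events_dataframe().to_csv(out / "events_applied.csv", index=False)
        ledger.gases_dataframe().to_csv(out / "gases.csv", index=False)
        residual = check_mass_balance(ledger, annual)
        (out / "run.log").write_text(
            f"stands: {len(stands)}\nyears: {config.start_year}-{config.end_year}\n"
            f"events applied: {len(ledger.events_applied)}\n"
            f"max mass-balance residual: {residual:.3e}\n"
        )
    return annual, ledger


def check_mass_balance(ledger: FluxLedger, annual: pd.DataFrame) -> float:
    """Largest relative mass-balance residual over all stand-years.

    For each stand and simulated year, the pool-total change must equal
    uptake minus atmosphere and products fluxes recorded in the ledger.
    """
    if annual.empty:
        return 0.0
    pool_cols = list(POOLS)
    totals = annual.set_index(["stand_id", "year"])[pool_cols].sum(axis=1)

    ldf = ledger.to_dataframe()
    if ldf.empty:
        uptake = atm = prod = pd.Series(dtype=float)
    else:
        uptake = (
            ldf[ldf["source"] == "atmosphere"].groupby(["stand_id", "year"])["mg_c"].sum()
        )
        atm = ldf[ldf["target"] == "atmosphere"].groupby(["stand_id", "year"])["mg_c"].sum()
        prod = ldf[ldf["target"] == "products"].groupby(["stand_id", "year"])["mg_c"].sum()

    worst = 0.0
    years = sorted(annual["year"].unique())
    for sid in annual["stand_id"].unique():
        for y0, y1 in zip(years[:-1], years[1:]):
            c0 = totals.get((sid, y0), 0.0)
            c1 = totals.get((sid, y1), 0.0)
            u = uptake.get((sid, y1), 0.0)
            a = atm.get((sid, y1), 0.0)
            pr = prod.get((sid, y1), 0.0)
            residual = abs((c1 - c0) - (u - a - pr)) / max(1.0, abs(c0))
            worst = max(worst, residual)
    return worst
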