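"""Initial pool state: spin-up for forest stands, class defaults with a
20-year transition for non-forest land.

Forest spin-up repeats a historic rotation -- grow the stand from age 0 for
the disturbance-return interval with full annual dynamics at the historic
temperature, then apply the stand-replacing fire matrix -- until the
belowground slow pool changes by less than the tolerance between successive
rotation ends.  The last known stand-replacing disturbance is a clear-cut,
after which the stand grows back to its inventory age.  The procedure is
fully deterministic.

Non-forest land starts from per-class belowground-slow defaults; after a
land-use change the stock moves linearly from the old class default to the
new one over a configurable transition (20 years by default) and then holds.
A stand afforested inside the window freezes its transition value at the
planting year and switches to forest dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .biomass_growth import live_carbon_trajectory
from .dom_dynamics import apply_turnover, decay_step, routing_matrix
from .disturbance_engine import apply_disturbance
from .model_core import (
    I_ATM,
    I_BG_SLOW,
    I_PRODUCTS,
    N_LIVE,
    LookupFailure,
    ParameterSet,
    PoolVector,
    StandRecord,
)


@dataclass(frozen=True)
class SpinupConfig:
    """Historic disturbance regime for one spatial unit."""

    return_interval: int = 50
    tolerance: float = 0.001
    max_rotations: int = 200
    last_pass_dtype: str = "HL"

    def __post_init__(self):
        if self.return_interval < 1:
            raise ValueError("return_interval must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_rotations < 1:
            raise ValueError("max_rotations must be >= 1")


@dataclass
class SpinupResult:
    pools: PoolVector
    converged: bool
    rotations: int


def _grow_years(
    pools: PoolVector,
    traj: np.ndarray,
    start_age: int,
    n_years: int,
    rates: np.ndarray,
    snag_fall: tuple,
    decay,
    applied: np.ndarray,
    routing: np.ndarray,
    area: float,
) -> PoolVector:
    """Run n_years of growth + turnover + decay from a given age (no events)."""
    x = pools
    max_a = traj.shape[0] - 1
    for a in range(start_age, start_age + n_years):
        a0 = min(a, max_a)
        a1 = min(a + 1, max_a)
        delta = np.maximum(traj[a1] - traj[a0], 0.0) * area
        x.data[:N_LIVE] += delta  # uptake; the atmosphere sink tracks emissions only
        x = apply_turnover(x, rates, snag_fall, routing=routing)
        x, _ = decay_step(x, decay, 0.0, applied=applied)
    return x


def spinup_stand(stand: StandRecord, p: ParameterSet, cfg: SpinupConfig, historic_temperature: float) -> SpinupResult:
    """Initialise a forest stand's pools by historic fire rotations.

    The returned pools have the atmosphere and products sinks zeroed: spin-up
    is pre-simulation history, and simulation sinks start from zero.
    """
    if not stand.is_forest:
        raise ValueError(f"stand {stand.stand_id} is not forested")
    if "FIRE" not in p.matrices:
        raise LookupFailure("parameter set has no FIRE matrix for spin-up")
    fire = p.matrices["FIRE"]
    last_pass = p.matrices[cfg.last_pass_dtype]
    rates = p.turnover.vector(p.turnover_class(stand))
    snag = p.snag_fall[stand.genus_class]
    applied = p.decay.applied_rates(historic_temperature)
    routing = routing_matrix()
    max_needed = max(cfg.return_interval, stand.age) + 1
    traj = live_carbon_trajectory(stand, p, max_needed)

    pools = PoolVector.zeros()
    prev_bg = None
    converged = False
    rotations = 0
    for rot in range(cfg.max_rotations):
        pools = _grow_years(
            pools, traj, 0, cfg.return_interval, rates, snag, p.decay, applied, routing, stand.area
        )
        pools, _, _, _ = apply_disturbance(pools, fire)
        rotations = rot + 1
        bg = pools.data[I_BG_SLOW]
        if prev_bg is not None:
            denom = bg if bg > 0 else 1.0
            if abs(bg - prev_bg) / denom < cfg.tolerance:
                converged = True
                break
        prev_bg = bg
    if not converged:
        warnings.warn(
            f"spin-up for stand {stand.stand_id} did not converge in "
            f"{cfg.max_rotations} rotations"
        )
    pools, _, _, _ = apply_disturbance(pools, last_pass)
    pools = _grow_years(
        pools, traj, 0, stand.age, rates, snag, p.decay, applied, routing, stand.area
    )
    pools.data[I_ATM] = 0.0
    pools.data[I_PRODUCTS] = 0.0
    return SpinupResult(pools=pools, converged=converged, rotations=rotations)


def nonforest_bgslow(
    table: dict,
    prev_class: str,
    new_class: str,
    years_since_conversion: float,
    transition_years: int = 20,
) -> float:
    """BG slow density (Mg C/ha) during/after a non-forest class transition.

    Linear from the old class default at year 0 to the new class default at
    ``transition_years``, constant afterwards.
    """
    if years_since_conversion < 0:
        raise ValueError("years_since_conversion must be >= 0")
    try:
        start = table[prev_class]
        end = table[new_class]
    except KeyError as e:
        raise LookupFailure(f"unknown soil class {e}") from None
    t = min(years_since_conversion, transition_years)
    return start + (end - start) * t / transition_years


def initialise_afforested_stand(
    stand: StandRecord,
    table: dict,
    p: ParameterSet,
    nonforest_class: str,
    prev_class: str | None = None,
    years_since_conversion: float | None = None,
) -> PoolVector:
    """Pools for a stand created by afforestation/natural expansion.

    Live pools and all DOM pools start at zero except the belowground slow
    pool, seeded with the prior non-forest value at the planting year (the
    non-forest transition is frozen from then on; forest dynamics take over).
    """
    if prev_class is not None and years_since_conversion is not None:
        density = nonforest_bgslow(
            table, prev_class, nonforest_class, years_since_conversion, p.transition_years
        )
    else:
        try:
            density = table[nonforest_class]
        except KeyError:
            raise LookupFailure(f"unknown soil class {nonforest_class!r}") from None
    pools = PoolVector.zeros()
    pools.data[I_BG_SLOW] = density * stand.area
    return pools
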