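"""Annual turnover, litterfall routing, temperature-dependent decay, snag
fall and slow-pool mixing.

Each live pool sheds a fixed annual fraction (the turnover rate) into its
dead-organic-matter targets: stem snags from merchantable stemwood, branch
snags from other wood, foliage litter into the aboveground very-fast pool,
and root turnover split 50/50 between the aboveground and belowground fast
(coarse roots) or very-fast (fine roots) pools.  Fallen snags feed the
medium (woody debris) and aboveground fast pools.

Every DOM pool then decays at base_rate * q10^((T - t_ref)/10), capped at 1.
A fraction p_atm of the decayed carbon is emitted; the remainder stabilises
into the aboveground or belowground slow pool.  Slow pools emit all of their
decayed carbon by default (a configured p_atm < 1 leaves the remainder in
place).  Finally a fixed fraction of the aboveground slow pool mixes down
into the belowground slow pool.  All steps conserve carbon exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    AG_DOM,
    DOM_POOLS,
    I_AG_FAST,
    I_AG_SLOW,
    I_AG_VERY_FAST,
    I_ATM,
    I_BG_FAST,
    I_BG_SLOW,
    I_BG_VERY_FAST,
    I_COARSE,
    I_FINE,
    I_FOLIAGE,
    I_MEDIUM,
    I_MERCH,
    I_OTHER,
    I_SNAG_BRANCH,
    I_SNAG_STEM,
    LIVE_POOLS,
    N_LIVE,
    N_POOLS,
    POOLS,
    SLOT,
    PoolVector,
)

# Default litterfall routing: live pool -> ((target, fraction), ...).
# Root turnover splits 50/50 between the AG and BG members of its speed class.
DEFAULT_ROUTING = {
    "merchantable_stemwood": (("snag_stem", 1.0),),
    "other_wood": (("snag_branch", 1.0),),
    "foliage": (("ag_very_fast", 1.0),),
    "fine_roots": (("ag_very_fast", 0.5), ("bg_very_fast", 0.5)),
    "coarse_roots": (("ag_fast", 0.5), ("bg_fast", 0.5)),
}

DOM_OFFSET = N_LIVE  # index of the first DOM pool
DOM_INDEX = {pool: SLOT[pool] for pool in DOM_POOLS}

# residue target (slow pool) per DOM pool; slow pools have no residue target
_RESIDUE_TARGET = np.array(
    [I_AG_SLOW if pool in AG_DOM else I_BG_SLOW if pool not in ("ag_slow", "bg_slow") else -1 for pool in DOM_POOLS]
)
_IS_SLOW = np.array([pool in ("ag_slow", "bg_slow") for pool in DOM_POOLS])
_TO_AG_SLOW = (~_IS_SLOW) & (_RESIDUE_TARGET == I_AG_SLOW)
_TO_BG_SLOW = (~_IS_SLOW) & (_RESIDUE_TARGET == I_BG_SLOW)


def routing_matrix(routing: dict | None = None) -> np.ndarray:
    """(5 live x N_POOLS) matrix of litterfall fractions; rows sum to 1."""
    routing = routing or DEFAULT_ROUTING
    R = np.zeros((N_LIVE, N_POOLS))
    for i, live in enumerate(LIVE_POOLS):
        for target, frac in routing[live]:
            R[i, SLOT[target]] += frac
        if abs(R[i].sum() - 1.0) > 1e-9:
            raise ValueError(f"routing for {live!r} does not sum to 1")
    return R


@dataclass
class TurnoverTable:
    """Annual turnover rate per (turnover class, live component).

    Bamboo, economic and shrub rows default to the evergreen broad-leaved row
    when absent (their litter dynamics are treated as evergreen broadleaf).
    """

    rates: dict

    def __post_init__(self):
        for tclass in ("bamboo", "economic", "shrub"):
            for comp in LIVE_POOLS:
                if (tclass, comp) not in self.rates and ("broadleaf_evergreen", comp) in self.rates:
                    self.rates[(tclass, comp)] = self.rates[("broadleaf_evergreen", comp)]

    def vector(self, tclass: str) -> np.ndarray:
        try:
            return np.array([self.rates[(tclass, comp)] for comp in LIVE_POOLS])
        except KeyError as e:
            raise KeyError(f"turnover table incomplete for class {tclass!r}: {e}") from None


def apply_turnover(
    pools: PoolVector,
    rates: np.ndarray | TurnoverTable,
    snag_fall: tuple = (0.0, 0.0),
    tclass: str | None = None,
    routing: np.ndarray | None = None,
    record: list | None = None,
) -> PoolVector:
    """One year of biomass turnover and snag fall.  Conserves carbon exactly.

    ``rates`` is either a length-5 vector over the live pools or a
    TurnoverTable plus ``tclass``.  ``snag_fall`` is (stem snag rate, branch
    snag rate).  If ``record`` is a list, (source, target, amount) transfers
    are appended to it.
    """
    if isinstance(rates, TurnoverTable):
        rates = rates.vector(tclass)
    R = routing if routing is not None else routing_matrix()
    x = pools.data.copy()
    moved = x[:N_LIVE] * np.asarray(rates)
    x[:N_LIVE] -= moved
    x[:N_POOLS] += moved @ R
    if record is not None:
        for i, live in enumerate(LIVE_POOLS):
            if moved[i] != 0.0:
                for j in range(N_POOLS):
                    if R[i, j] != 0.0:
                        record.append((live, POOLS[j], moved[i] * R[i, j]))
    s_stem, s_branch = snag_fall
    fall_stem = x[I_SNAG_STEM] * s_stem
    fall_branch = x[I_SNAG_BRANCH] * s_branch
    x[I_SNAG_STEM] -= fall_stem
    x[I_MEDIUM] += fall_stem
    x[I_SNAG_BRANCH] -= fall_branch
    x[I_AG_FAST] += fall_branch
    if record is not None:
        if fall_stem != 0.0:
            record.append(("snag_stem", "medium", fall_stem))
        if fall_branch != 0.0:
            record.append(("snag_branch", "ag_fast", fall_branch))
    return PoolVector(x)


def temperature_modifier(temperature: float, t_ref: float, q10: float) -> float:
    """Q10 decay multiplier: q10 ** ((T - t_ref) / 10)."""
    if q10 <= 0:
        raise ValueError("q10 must be > 0")
    return float(q10 ** ((temperature - t_ref) / 10.0))


@dataclass
class DecayParameters:
    """Per-DOM-pool decay: base rate at t_ref, Q10, atmosphere fraction.

    ``p_atm`` is the fraction of decayed carbon emitted; the remainder
    stabilises into the matching slow pool.  For the slow pools themselves a
    p_atm below one leaves the non-emitted share in place (no further
    stabilisation target), so they effectively decay at p_atm * rate.
    ``slow_mixing_rate`` moves AG slow carbon into BG slow each year.
    """

    base_rate: np.ndarray
    t_ref: np.ndarray
    q10: np.ndarray
    p_atm: np.ndarray
    slow_mixing_rate: float = 0.006

    @classmethod
    def from_frame(cls, df: pd.DataFrame, slow_mixing_rate: float = 0.006) -> "DecayParameters":
        df = df.set_index("pool").reindex(list(DOM_POOLS))
        if df.isna().any().any():
            missing = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"decay table missing pools: {missing}")
        return cls(
            base_rate=df["base_rate"].to_numpy(dtype=float),
            t_ref=df["t_ref"].to_numpy(dtype=float),
            q10=df["q10"].to_numpy(dtype=float),
            p_atm=df["p_atm"].to_numpy(dtype=float),
            slow_mixing_rate=slow_mixing_rate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pool": list(DOM_POOLS),
                "base_rate": self.base_rate,
                "t_ref": self.t_ref,
                "q10": self.q10,
                "p_atm": self.p_atm,
            }
        )

    def validate(self) -> list[str]:
        v = []
        for i, pool in enumerate(DOM_POOLS):
            if not (0.0 <= self.base_rate[i] <= 1.0):
                v.append(f"decay[{pool}].base_rate={self.base_rate[i]} outside [0,1]")
            if self.q10[i] <= 0:
                v.append(f"decay[{pool}].q10={self.q10[i]} must be > 0")
            if not (0.0 <= self.p_atm[i] <= 1.0):
                v.append(f"decay[{pool}].p_atm={self.p_atm[i]} outside [0,1]")
        if not (0.0 <= self.slow_mixing_rate <= 1.0):
            v.append(f"slow_mixing_rate={self.slow_mixing_rate} outside [0,1]")
        return v

    def applied_rates(self, temperature: float) -> np.ndarray:
        """Temperature-modified decay rates, capped at 1."""
        mod = self.q10 ** ((temperature - self.t_ref) / 10.0)
        return np.minimum(self.base_rate * mod, 1.0)


def decay_step(
    pools: PoolVector,
    d: DecayParameters,
    temperature: float,
    record: list | None = None,
    applied: np.ndarray | None = None,
) -> tuple:
    """One year of DOM decay plus slow mixing.

    Returns (new pools, carbon emitted to atmosphere).  ``applied`` lets a
    caller reuse precomputed temperature-modified rates.  Conserves carbon:
    total pool change + emission = 0.
    """
    k = applied if applied is not None else d.applied_rates(temperature)
    x = pools.data.copy()
    dom = x[DOM_OFFSET:N_POOLS]
    decayed = dom * k
    emitted = decayed * d.p_atm
    residue = decayed * (1.0 - d.p_atm)
    # slow pools retain their non-emitted share: only the emission leaves
    removal = np.where(_IS_SLOW, emitted, decayed)
    dom -= removal
    to_atm = float(emitted.sum())
    ag_residue = float(residue[_TO_AG_SLOW].sum())
    bg_residue = float(residue[_TO_BG_SLOW].sum())
    x[I_AG_SLOW] += ag_residue
    x[I_BG_SLOW] += bg_residue
    x[I_ATM] += to_atm
    if record is not None:
        for i, pool in enumerate(DOM_POOLS):
            if emitted[i] != 0.0:
                record.append((pool, "atmosphere", float(emitted[i])))
            if not _IS_SLOW[i] and residue[i] != 0.0:
                record.append((pool, POOLS[_RESIDUE_TARGET[i]], float(residue[i])))
    mixed = x[I_AG_SLOW] * d.slow_mixing_rate
    x[I_AG_SLOW] -= mixed
    x[I_BG_SLOW] += mixed
    if record is not None and mixed != 0.0:
        record.append(("ag_slow", "bg_slow", float(mixed)))
    return PoolVector(x), to_atm


def dom_equilibrium_check(input_rate: float, pool_rate: float) -> float:
    """Analytic steady state of x <- x (1 - k) + u: returns u / k.

    Used as the independent oracle for spin-up and convergence tests.
    """
    if not (0.0 < pool_rate <= 1.0):
        raise ValueError("pool_rate must be in (0, 1]")
    return input_rate / pool_rate
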