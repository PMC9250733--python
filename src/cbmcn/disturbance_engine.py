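"""Disturbance classification, matrix application, stand reset and GHG
speciation.

Nine disturbance / land-use-change types are recognised: afforestation (AF)
and natural expansion (NE) create forest on non-forest land; regeneration
logging (RL) and harvest logging (HL) reset forest stands in place
(distinguished by whether the stand had reached its species harvest age);
deforestation for agriculture (DFA) or built-up land (DFB) and forest
conversion to grassland (FCG), water/wetland (FCW) or bare land (FDB) move
forest out of the forest land-use class.

Each type carries a disturbance matrix: for every source pool, the
proportions of its carbon routed to each pool, to the atmosphere, and to the
forest products sector.  Rows sum to one, so application conserves carbon.
Atmosphere fluxes from rows flagged as burning are speciated into CO2, CO
and CH4 by carbon fraction (plus N2O per unit burned carbon); all other
emissions are pure CO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    DTYPES,
    I_ATM,
    I_PRODUCTS,
    N_LIVE,
    N_POOLS,
    N_SLOTS,
    POOLS,
    SLOT,
    DisturbanceEvent,
    PoolVector,
    StandRecord,
    ValidationError,
)

# molar mass of each gas per mole of carbon
CO2_PER_C = 44.0 / 12.0
CO_PER_C = 28.0 / 12.0
CH4_PER_C = 16.0 / 12.0

BURNING_DTYPES = ("RL", "HL", "DFA", "DFB")
NON_BURNING_DTYPES = ("AF", "NE", "FCG", "FCW", "FDB")

DEFAULT_GWP = {"co2": 1.0, "ch4": 21.0, "co": 0.0, "n2o": 310.0}


@dataclass
class DisturbanceMatrix:
    """Square-plus-sinks proportion matrix for one disturbance type.

    ``matrix`` is (N_POOLS x N_SLOTS): each source-pool row gives the
    proportion routed to every pool plus the atmosphere and products sinks.
    ``is_burning`` flags, per source row, whether that row's atmosphere flux
    is combustion (and so subject to non-CO2 speciation).
    """

    dtype: str
    matrix: np.ndarray
    is_burning: np.ndarray = None
    stand_replacing: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_POOLS, N_SLOTS):
            raise ValueError(f"matrix must be {N_POOLS}x{N_SLOTS}")
        if self.is_burning is None:
            self.is_burning = np.zeros(N_POOLS, dtype=bool)
        self.is_burning = np.asarray(self.is_burning, dtype=bool)

    @classmethod
    def identity(cls, dtype: str) -> "DisturbanceMatrix":
        m = np.zeros((N_POOLS, N_SLOTS))
        m[:, :N_POOLS] = np.eye(N_POOLS)
        return cls(dtype=dtype, matrix=m)

    @classmethod
    def from_frame(cls, dtype: str, df: pd.DataFrame) -> "DisturbanceMatrix":
        """Build from long-form rows (source_pool, target, proportion[, is_burning]).

        Unlisted source pools keep their carbon (identity rows).
        """
        m = np.zeros((N_POOLS, N_SLOTS))
        m[:, :N_POOLS] = np.eye(N_POOLS)
        burning = np.zeros(N_POOLS, dtype=bool)
        listed = set()
        for row in df.itertuples(index=False):
            i = SLOT[row.source_pool]
            if i >= N_POOLS:
                raise ValueError(f"{dtype}: source {row.source_pool!r} is a sink")
            if row.source_pool not in listed:
                m[i, :] = 0.0
                listed.add(row.source_pool)
            m[i, SLOT[row.target]] += float(row.proportion)
            if "is_burning" in df.columns and bool(row.is_burning):
                burning[i] = True
        sr = bool(df["stand_replacing"].iloc[0]) if "stand_replacing" in df.columns else False
        return cls(dtype=dtype, matrix=m, is_burning=burning, stand_replacing=sr)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, source in enumerate(POOLS):
            for j in range(N_SLOTS):
                if self.matrix[i, j] != 0.0:
                    rows.append(
                        {
                            "source_pool": source,
                            "target": (POOLS + ("atmosphere", "products"))[j],
                            "proportion": self.matrix[i, j],
                            "is_burning": bool(self.is_burning[i]),
                            "stand_replacing": self.stand_replacing,
                        }
                    )
        return pd.DataFrame(rows)

    def validate(self) -> list[str]:
        v = []
        sums = self.matrix.sum(axis=1)
        for i, source in enumerate(POOLS):
            if abs(sums[i] - 1.0) > 1e-9:
                v.append(f"matrix {self.dtype}: row {source!r} sums to {sums[i]:.6f}")
        if (self.matrix < -1e-12).any() or (self.matrix > 1.0 + 1e-12).any():
            v.append(f"matrix {self.dtype}: entries outside [0, 1]")
        if self.stand_replacing:
            live_retained = self.matrix[:N_LIVE, :N_LIVE].sum()
            if live_retained > 1e-9:
                v.append(
                    f"matrix {self.dtype}: flagged stand-replacing but retains "
                    f"{live_retained:.4f} live proportion"
                )
        return v


def classify_transition(prev: StandRecord, cur: StandRecord, harvest_age: int) -> str | None:
    """Classify the transition between two consecutive-year states of a stand.

    Returns one of the nine disturbance types or None (undisturbed).
    """
    if prev.stand_id != cur.stand_id:
        raise ValueError("records refer to different stands")
    if not prev.is_forest and cur.is_forest:
        return "AF" if cur.origin == "planted" else "NE"
    if prev.is_forest and not cur.is_forest:
        return {
            "cropland_paddy": "DFA",
            "cropland_dryland": "DFA",
            "built_up": "DFB",
            "grassland": "FCG",
            "wetland_water": "FCW",
            "bare": "FDB",
        }[cur.land_use]
    if prev.is_forest and cur.is_forest and cur.age <= 1 and prev.age >= 1:
        return "HL" if prev.age >= harvest_age else "RL"
    return None


def apply_disturbance(pools: PoolVector, m: DisturbanceMatrix, record: list | None = None) -> tuple:
    """Apply a disturbance matrix simultaneously to all pools.

    All transfers are computed from pre-disturbance stocks.  Returns
    (new pools, to_atmosphere, to_products, burned_carbon) where
    ``burned_carbon`` is the part of the atmosphere flux sourced from rows
    flagged as burning.  Conserves carbon exactly.
    """
    problems = m.validate()
    if problems:
        raise ValidationError("; ".join(problems))
    x = pools.data.copy()
    stocks = pools.data[:N_POOLS]
    out = stocks @ m.matrix  # length N_SLOTS
    x[:N_POOLS] = out[:N_POOLS]
    to_atm = float(out[I_ATM])
    to_products = float(out[I_PRODUCTS])
    burned = float((stocks * m.matrix[:, I_ATM] * m.is_burning).sum())
    x[I_ATM] += to_atm
    x[I_PRODUCTS] += to_products
    if record is not None:
        targets = POOLS + ("atmosphere", "products")
        for i, source in enumerate(POOLS):
            if stocks[i] == 0.0:
                continue
            for j in range(N_SLOTS):
                amt = stocks[i] * m.matrix[i, j]
                if amt != 0.0 and not (j == i and m.matrix[i, j] == 1.0):
                    record.append((source, targets[j], amt))
    return PoolVector(x), to_atm, to_products, burned


def post_disturbance_reset(
    stand: StandRecord,
    dtype: str,
    event: DisturbanceEvent,
    default_cropland: str = "cropland_dryland",
) -> StandRecord:
    """Return the post-disturbance stand record (age reset, land-use change)."""
    if dtype not in DTYPES:
        raise ValueError(f"unknown dtype {dtype!r}")
    if event.dtype != dtype:
        raise ValueError(f"event dtype {event.dtype!r} does not match {dtype!r}")
    if dtype in ("AF", "NE"):
        return stand.with_(
            land_use="forest",
            forest_type=_forest_type_hint(event.post_species or stand.species),
            age=1,
            origin="planted" if dtype == "AF" else "natural",
            species=event.post_species or stand.species,
        )
    if dtype in ("RL", "HL"):
        return stand.with_(
            age=1,
            species=event.post_species or stand.species,
            origin=event.post_origin or stand.origin,
        )
    target = {
        "DFA": event.post_land_use or default_cropland,
        "DFB": "built_up",
        "FCG": "grassland",
        "FCW": "wetland_water",
        "FDB": "bare",
    }[dtype]
    return stand.with_(land_use=target, forest_type=None, last_lucc_year=event.year)


def _forest_type_hint(species: str) -> str:
    # events carry species, not forest type; infer non-arbour types by name
    s = (species or "").lower()
    for ft in ("bamboo", "economic", "shrub"):
        if ft in s:
            return ft
    return "arbour"


@dataclass
class EmissionFactors:
    """Gas speciation of burned carbon.

    ``co2_frac``, ``co_frac`` and ``ch4_frac`` partition burned carbon by
    mass of C and must sum to one; ``n2o_per_c`` is Mg N2O emitted per Mg of
    burned carbon.
    """

    co2_frac: float = 0.90
    co_frac: float = 0.09
    ch4_frac: float = 0.01
    n2o_per_c: float = 5.7e-4

    def validate(self, raise_: bool = False) -> list[str]:
        v = []
        if abs(self.co2_frac + self.co_frac + self.ch4_frac - 1.0) > 1e-9:
            v.append("burned-carbon gas fractions must sum to 1")
        if min(self.co2_frac, self.co_frac, self.ch4_frac, self.n2o_per_c) < 0:
            v.append("emission factors must be >= 0")
        if raise_ and v:
            raise ValidationError("; ".join(v))
        return v


def speciate_emissions(burned_c: float, unburned_emitted_c: float, f: EmissionFactors) -> dict:
    """Convert emitted carbon to gas masses (Mg of each gas).

    Non-combustion emissions are entirely CO2; burned carbon splits into
    CO2/CO/CH4 by carbon fraction, converted by molar mass ratios, with N2O
    proportional to burned carbon.
    """
    if burned_c < 0 or unburned_emitted_c < 0:
        raise ValueError("carbon masses must be >= 0")
    f.validate(raise_=True)
    return {
        "co2": (unburned_emitted_c + burned_c * f.co2_frac) * CO2_PER_C,
        "co": burned_c * f.co_frac * CO_PER_C,
        "ch4": burned_c * f.ch4_frac * CH4_PER_C,
        "n2o": burned_c * f.n2o_per_c,
    }


def co2_equivalent(gases: dict, gwp: dict | None = None) -> float:
    """CO2-equivalent mass: sum of gas masses weighted by their GWP factors."""
    gwp = gwp or DEFAULT_GWP
    return float(sum(mass * gwp[gas] for gas, mass in gases.items()))
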