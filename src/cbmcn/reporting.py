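"""Aggregation of pools and ledgers into the model's reporting surfaces.

The 14 model pools roll up into the five IPCC Good Practice Guidance (GPG)
forest carbon pools -- aboveground biomass, belowground biomass, dead wood,
litter, and soil organic matter.  On top of that sit: per-year stock and
density tables with change and trend-slope summaries, per-disturbance-type
area / stock-change / expenditure summaries, derived shares and annual
rates, and greenhouse-gas totals with CO2-equivalent aggregation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annual_simulator import FluxLedger
from .disturbance_engine import DEFAULT_GWP, co2_equivalent
from .model_core import DOM_POOLS, DTYPES, LIVE_POOLS, POOLS

# Model pool -> GPG pool.  Dead coarse roots (bg_fast) count as dead wood;
# the AG slow (surface humus) pool counts as litter; soil organic matter is
# the belowground very-fast + slow pools.
GPG_MAPPING = {
    "merchantable_stemwood": "agb",
    "other_wood": "agb",
    "foliage": "agb",
    "coarse_roots": "bgb",
    "fine_roots": "bgb",
    "snag_stem": "dead_wood",
    "snag_branch": "dead_wood",
    "medium": "dead_wood",
    "bg_fast": "dead_wood",
    "ag_very_fast": "litter",
    "ag_fast": "litter",
    "ag_slow": "litter",
    "bg_very_fast": "soil",
    "bg_slow": "soil",
}
GPG_POOLS = ("agb", "bgb", "dead_wood", "litter", "soil")

MG_PER_TG = 1e6


def aggregate_gpg(
    annual_pools: pd.DataFrame,
    mapping: dict | None = None,
    areas: dict | None = None,
    forest_only: bool = True,
) -> pd.DataFrame:
    """Per-year GPG stocks (Tg C) and densities (Mg C/ha).

    ``annual_pools`` has one row per stand-year with the model pool columns
    in Mg C and an ``area_ha`` column.  ``areas`` optionally overrides the
    per-year forest area used for densities; by default it is the summed
    area of forest stands that year.
    """
    mapping = mapping or GPG_MAPPING
    unmapped = [pool for pool in POOLS if pool not in mapping]
    if unmapped:
        raise KeyError(f"model pools not mapped to a GPG pool: {unmapped}")
    df = annual_pools
    if forest_only and "land_use" in df.columns:
        df = df[df["land_use"] == "forest"]
    rows = []
    for year, grp in df.groupby("year"):
        row = {"year": int(year)}
        for gpg in GPG_POOLS:
            members = [pool for pool, target in mapping.items() if target == gpg]
            row[gpg] = grp[members].to_numpy().sum() / MG_PER_TG
        row["total"] = sum(row[gpg] for gpg in GPG_POOLS)
        area = areas[year] if areas is not None else grp["area_ha"].sum()
        row["area_ha"] = float(area)
        for gpg in GPG_POOLS + ("total",):
            row[f"{gpg}_density"] = row[gpg] * MG_PER_TG / area if area > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("year").sort_index()


def pool_shares(gpg_row: pd.Series) -> dict:
    """Shares (%) of the total ecosystem stock: living biomass, soil, AG DOM."""
    total = gpg_row["total"]
    return {
        "living_biomass_pct": (gpg_row["agb"] + gpg_row["bgb"]) / total * 100.0,
        "soil_pct": gpg_row["soil"] / total * 100.0,
        "ag_dom_pct": (gpg_row["dead_wood"] + gpg_row["litter"]) / total * 100.0,
    }


def stock_change_summary(
    gpg: pd.DataFrame, start: int, end: int, with_slope: bool = True
) -> pd.DataFrame:
    """Start/end stocks, change, and (optionally) the OLS trend per GPG pool.

    The slope is the ordinary-least-squares regression of stock on calendar
    year with a two-sided t-test p-value; it needs at least three years.
    """
    cols = list(GPG_POOLS) + ["total"]
    if with_slope and len(gpg.index) < 3:
        raise ValueError("slope needs at least 3 years of stocks")
    span = end - start
    out = {}
    for col in cols:
        series = gpg[col]
        entry = {
            "start": series.loc[start],
            "end": series.loc[end],
            "change": series.loc[end] - series.loc[start],
        }
        entry["annual_mean_rate"] = entry["change"] / span if span else np.nan
        if with_slope:
            fit = stats.linregress(gpg.index.to_numpy(dtype=float), series.to_numpy())
            entry["slope"] = fit.slope
            entry["p_value"] = fit.pvalue
        out[col] = entry
    return pd.DataFrame(out).T


SUMMARY_COLUMNS = [
    "area_1e4_ha",
    "biomass_change_gg",
    "dom_change_gg",
    "total_change_gg",
    "atmosphere_gg",
    "products_gg",
    "expenditure_gg",
]


def disturbance_summary(ledger: FluxLedger) -> pd.DataFrame:
    """Per-disturbance-type area, stock changes and carbon expenditures.

    Stock changes are post-minus-pre over the event step, derived from the
    ledger's disturbance transfer records (flows from the atmosphere count as
    uptake).  Areas are in 1e4 ha, carbon in Gg C.  A grand-total row closes
    the table; total change = biomass + DOM change and expenditure =
    atmosphere + products hold exactly by construction.
    """
    live = set(LIVE_POOLS)
    dom = set(DOM_POOLS)
    acc = {dt: dict.fromkeys(SUMMARY_COLUMNS, 0.0) for dt in DTYPES}
    for ev in ledger.events_applied:
        acc[ev["dtype"]]["area_1e4_ha"] += ev["area_ha"] / 1e4
    for year, sid, process, source, target, amount in ledger.records:
        if not process.startswith("disturbance:"):
            continue
        dt = process.split(":", 1)[1]
        gg = amount / 1e3
        row = acc[dt]
        if source in live:
            row["biomass_change_gg"] -= gg
        elif source in dom:
            row["dom_change_gg"] -= gg
        if target in live:
            row["biomass_change_gg"] += gg
        elif target in dom:
            row["dom_change_gg"] += gg
        elif target == "atmosphere":
            row["atmosphere_gg"] += gg
        elif target == "products":
            row["products_gg"] += gg
    rows = []
    for dt in DTYPES:
        row = acc[dt]
        row["total_change_gg"] = row["biomass_change_gg"] + row["dom_change_gg"]
        row["expenditure_gg"] = row["atmosphere_gg"] + row["products_gg"]
        rows.append({"dtype": dt, **row})
    df = pd.DataFrame(rows).set_index("dtype")
    df.loc["Total"] = df.sum(axis=0)
    return df[SUMMARY_COLUMNS]


def shares_and_rates(
    summary: pd.DataFrame, span_years: int, total_ecosystem_change_tg: float | None = None
) -> dict:
    """Derived statistics from a disturbance summary.

    Returns raw values plus a ``printed`` dict rounded the way such tables
    are usually reported (area and per-type shares to one decimal, aggregate
    shares to integers, annual rates to two decimals).  Zero denominators
    yield NaN markers rather than exceptions.
    """
    body = summary.drop(index="Total", errors="ignore")
    total_area = summary.loc["Total", "area_1e4_ha"] if "Total" in summary.index else body["area_1e4_ha"].sum()
    total_exp = summary.loc["Total", "expenditure_gg"] if "Total" in summary.index else body["expenditure_gg"].sum()
    total_atm = summary.loc["Total", "atmosphere_gg"] if "Total" in summary.index else body["atmosphere_gg"].sum()
    total_change = summary.loc["Total", "total_change_gg"] if "Total" in summary.index else body["total_change_gg"].sum()

    def _share(x, denom):
        return float(x) / denom * 100.0 if denom else float("nan")

    area_shares = {dt: _share(body.loc[dt, "area_1e4_ha"], total_area) for dt in body.index}
    exp_shares = {dt: _share(body.loc[dt, "expenditure_gg"], total_exp) for dt in body.index}
    out = {
        "area_share_pct": area_shares,
        "expenditure_share_pct": exp_shares,
        "atmosphere_share_of_expenditure_pct": _share(total_atm, total_exp),
        "annual_expenditure_tg": total_exp / 1e3 / span_years if span_years else float("nan"),
        "annual_stock_change_tg": total_change / 1e3 / span_years if span_years else float("nan"),
    }
    if total_ecosystem_change_tg:
        out["decrease_share_of_total_change_pct"] = _share(
            -total_change / 1e3, total_ecosystem_change_tg
        )
    def _round(v, ndigits=None):
        if isinstance(v, float) and np.isnan(v):
            return v
        return round(v, ndigits) if ndigits is not None else round(v)

    out["printed"] = {
        "area_share_pct": {dt: _round(v, 1) for dt, v in area_shares.items()},
        "expenditure_share_pct": {dt: _round(v) for dt, v in exp_shares.items()},
        "atmosphere_share_of_expenditure_pct": _round(out["atmosphere_share_of_expenditure_pct"]),
        "annual_expenditure_tg": _round(out["annual_expenditure_tg"], 2),
        "annual_stock_change_tg": _round(out["annual_stock_change_tg"], 2),
    }
    if "decrease_share_of_total_change_pct" in out:
        out["printed"]["decrease_share_of_total_change_pct"] = _round(
            out["decrease_share_of_total_change_pct"]
        )
    return out


def ghg_summary(ledger: FluxLedger, gwp: dict | None = None) -> dict:
    """Per-gas emission totals (Mg of gas), per-dtype breakdown, and CO2e."""
    gwp = gwp or DEFAULT_GWP
    gases = ledger.gases_dataframe()
    totals = {gas: float(gases[gas].sum()) if not gases.empty else 0.0 for gas in ("co2", "co", "ch4", "n2o")}
    by_dtype = {}
    if not gases.empty:
        for dt, grp in gases.groupby("dtype"):
            masses = {gas: float(grp[gas].sum()) for gas in ("co2", "co", "ch4", "n2o")}
            by_dtype[dt] = {**masses, "co2e": co2_equivalent(masses, gwp)}
    return {
        "totals": totals,
        "co2e": co2_equivalent(totals, gwp),
        "by_dtype": by_dtype,
    }
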