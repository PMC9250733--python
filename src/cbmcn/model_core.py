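"""Shared domain types, pool layout, and tabular I/O.

The simulator tracks carbon per stand in five live biomass pools and nine
dead-organic-matter (DOM) pools, plus two cumulative sinks (atmosphere and
forest products).  Snag pools carry the stand's genus class (softwood vs
hardwood lead species), so across the two genus classes the DOM layout
matches the eleven-DOM-pool convention of CBM-CFS3-style carbon budget
models.

All inputs are plain CSV tables plus one YAML manifest: the stand inventory
(one row per stand, modelled on a planning-and-design forest survey schema),
a per-spatial-unit temperature series, a disturbance/land-use-change event
schedule, and a parameter directory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Pool layout
# ---------------------------------------------------------------------------

LIVE_POOLS = (
    "merchantable_stemwood",
    "other_wood",
    "foliage",
    "coarse_roots",
    "fine_roots",
)
DOM_POOLS = (
    "snag_stem",
    "snag_branch",
    "medium",
    "ag_fast",
    "ag_very_fast",
    "ag_slow",
    "bg_fast",
    "bg_very_fast",
    "bg_slow",
)
SINKS = ("atmosphere", "products")
POOLS = LIVE_POOLS + DOM_POOLS
SLOTS = POOLS + SINKS

N_LIVE = len(LIVE_POOLS)
N_POOLS = len(POOLS)
N_SLOTS = len(SLOTS)

SLOT = {name: i for i, name in enumerate(SLOTS)}
I_MERCH, I_OTHER, I_FOLIAGE, I_COARSE, I_FINE = range(5)
I_SNAG_STEM = SLOT["snag_stem"]
I_SNAG_BRANCH = SLOT["snag_branch"]
I_MEDIUM = SLOT["medium"]
I_AG_FAST = SLOT["ag_fast"]
I_AG_VERY_FAST = SLOT["ag_very_fast"]
I_AG_SLOW = SLOT["ag_slow"]
I_BG_FAST = SLOT["bg_fast"]
I_BG_VERY_FAST = SLOT["bg_very_fast"]
I_BG_SLOW = SLOT["bg_slow"]
I_ATM = SLOT["atmosphere"]
I_PRODUCTS = SLOT["products"]

# DOM pools whose decay residue stabilises into the AG slow pool vs BG slow
AG_DOM = ("snag_stem", "snag_branch", "medium", "ag_fast", "ag_very_fast")
BG_DOM = ("bg_fast", "bg_very_fast")
SLOW_DOM = ("ag_slow", "bg_slow")


class PoolVector:
    """Carbon mass (Mg C) per pool for one stand, plus cumulative sinks."""

    __slots__ = ("data",)

    def __init__(self, data=None):
        if data is None:
            self.data = np.zeros(N_SLOTS)
        else:
            self.data = np.asarray(data, dtype=float).copy()
            if self.data.shape != (N_SLOTS,):
                raise ValueError(f"PoolVector needs {N_SLOTS} slots")

    @classmethod
    def zeros(cls) -> "PoolVector":
        return cls()

    def __getitem__(self, name: str) -> float:
        return float(self.data[SLOT[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.data[SLOT[name]] = value

    def copy(self) -> "PoolVector":
        return PoolVector(self.data)

    def total_pools(self) -> float:
        return float(self.data[:N_POOLS].sum())

    def total_live(self) -> float:
        return float(self.data[:N_LIVE].sum())

    def total_dom(self) -> float:
        return float(self.data[N_LIVE:N_POOLS].sum())

    def total_with_sinks(self) -> float:
        return float(self.data.sum())

    def as_dict(self) -> dict:
        return {name: float(self.data[i]) for name, i in SLOT.items()}

    def __repr__(self) -> str:  # pragma: no cover
        nz = {k: round(v, 4) for k, v in self.as_dict().items() if v != 0.0}
        return f"PoolVector({nz})"


# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

LAND_USES = (
    "forest",
    "cropland_paddy",
    "cropland_dryland",
    "grassland",
    "wetland_water",
    "built_up",
    "bare",
)
NON_FOREST_LAND_USES = tuple(lu for lu in LAND_USES if lu != "forest")
FOREST_TYPES = ("arbour", "bamboo", "economic", "shrub")
ORIGINS = ("planted", "natural")
GENUS_CLASSES = ("softwood", "hardwood")
AGE_GROUPS = ("YF", "MAF", "NMF", "MF", "PMF")
DTYPES = ("AF", "NE", "RL", "HL", "DFA", "DFB", "FCG", "FCW", "FDB")
TURNOVER_CLASSES = (
    "coniferous",
    "broadleaf_evergreen",
    "broadleaf_deciduous",
    "bamboo",
    "economic",
    "shrub",
)
SOIL_CLASSES = (
    "paddy",
    "dryland",
    "grassland",
    "wetland",
    "inland_water",
    "built_up",
    "bare",
)
# land_use -> non-forest soil class (inventory schema merges water and wetland)
LAND_USE_TO_SOIL_CLASS = {
    "cropland_paddy": "paddy",
    "cropland_dryland": "dryland",
    "grassland": "grassland",
    "wetland_water": "wetland",
    "built_up": "built_up",
    "bare": "bare",
}

INVENTORY_COLUMNS = [
    "stand_id",
    "spu_id",
    "species",
    "genus_class",
    "forest_type",
    "origin",
    "land_use",
    "age",
    "area_ha",
    "climatic_zone",
    "site_quality",
    "rocky_desertification",
    "last_lucc_year",
]


class SchemaError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class LookupFailure(KeyError):
    pass


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class StandRecord:
    """One inventory stand: classifiers, age, area, land use, forest type."""

    stand_id: str
    spu_id: str
    species: str
    genus_class: str
    forest_type: str | None
    origin: str
    land_use: str
    age: int
    area: float
    climatic_zone: str = "mid_subtropical"
    site_quality: str = "2"
    rocky_desertification: str = "none"
    last_lucc_year: int | None = None

    @property
    def classifier_key(self) -> str:
        """Five-level key: species, climatic zone, site quality, origin, rocky type."""
        return "|".join(
            (
                self.species,
                self.climatic_zone,
                str(self.site_quality),
                self.origin,
                self.rocky_desertification,
            )
        )

    @property
    def is_forest(self) -> bool:
        return self.land_use == "forest"

    def validate(self) -> list[str]:
        v = []
        if self.area <= 0:
            v.append(f"stand {self.stand_id}: area must be > 0, got {self.area}")
        if self.age < 0 or int(self.age) != self.age:
            v.append(f"stand {self.stand_id}: age must be a whole number >= 0")
        if self.land_use not in LAND_USES:
            v.append(f"stand {self.stand_id}: unknown land_use {self.land_use!r}")
        if self.origin not in ORIGINS:
            v.append(f"stand {self.stand_id}: unknown origin {self.origin!r}")
        if self.genus_class not in GENUS_CLASSES:
            v.append(f"stand {self.stand_id}: unknown genus_class {self.genus_class!r}")
        if self.land_use == "forest":
            if self.forest_type not in FOREST_TYPES:
                v.append(
                    f"stand {self.stand_id}: forest stand needs a forest_type, "
                    f"got {self.forest_type!r}"
                )
        elif self.forest_type is not None:
            v.append(
                f"stand {self.stand_id}: non-forest stand must not carry a forest_type"
            )
        return v

    def with_(self, **kwargs) -> "StandRecord":
        return replace(self, **kwargs)


@dataclass
class ClimateSeries:
    """Mean annual temperature (deg C) per spatial unit, by calendar year."""

    spu_id: str
    temperatures: dict[int, float]
    historic_mean: float | None = None

    def temperature(self, year: int) -> float:
        try:
            return self.temperatures[year]
        except KeyError:
            raise LookupFailure(
                f"no temperature for SPU {self.spu_id!r} in year {year}"
            ) from None

    def historic(self) -> float:
        """Historic spin-up temperature; defaults to the earliest decade's mean."""
        if self.historic_mean is not None:
            return self.historic_mean
        years = sorted(self.temperatures)
        first = years[: min(10, len(years))]
        return float(np.mean([self.temperatures[y] for y in first]))


@dataclass(frozen=True)
class DisturbanceEvent:
    year: int
    stand_id: str
    dtype: str
    post_land_use: str | None = None
    post_species: str | None = None
    post_origin: str | None = None

    def validate(self) -> list[str]:
        v = []
        if self.dtype not in DTYPES:
            v.append(f"event {self.stand_id}@{self.year}: unknown dtype {self.dtype!r}")
        expected = {
            "AF": "forest",
            "NE": "forest",
            "RL": "forest",
            "HL": "forest",
            "DFA": ("cropland_paddy", "cropland_dryland"),
            "DFB": "built_up",
            "FCG": "grassland",
            "FCW": "wetland_water",
            "FDB": "bare",
        }.get(self.dtype)
        if expected is not None and self.post_land_use is not None:
            ok = (
                self.post_land_use in expected
                if isinstance(expected, tuple)
                else self.post_land_use == expected
            )
            if not ok:
                v.append(
                    f"event {self.stand_id}@{self.year}: post_land_use "
                    f"{self.post_land_use!r} inconsistent with {self.dtype}"
                )
        return v


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All coefficient tables the simulator consumes.

    Keys and units:

    * ``growth_curves`` -- classifier_key -> GrowthCurve (m3/ha vs age).
    * ``allocation_models`` -- species -> AllocationModel (stem power model +
      multinomial-logit component proportions).
    * ``root_models`` -- genus_class -> RootModel (total roots from AGB and a
      saturating fine-root fraction).
    * ``merch_proportion`` -- species -> merchantable fraction of stem+bark in
      mature/post-mature stands, in (0, 1].
    * ``c_content`` -- (species, component) -> g C / g dry matter.
    * ``turnover`` -- TurnoverTable: turnover class x live component -> yr-1.
    * ``snag_fall`` -- genus_class -> (stem snag fall, branch snag fall) yr-1.
    * ``decay`` -- DecayParameters over the nine DOM pools + slow mixing.
    * ``matrices`` -- dtype -> DisturbanceMatrix ("FIRE" is the spin-up regime).
    * ``nonarbour_series`` -- species -> NonArbourSeries (age -> biomass per ha).
    * ``soil_defaults`` -- non-forest soil class -> BG slow density (Mg C/ha).
    * ``age_groups`` -- species -> four increasing thresholds splitting ages
      into YF / MAF / NMF / MF / PMF.
    * ``harvest_age`` -- species -> years.
    * ``emission_factors`` / ``gwp`` -- gas speciation of burned carbon and
      CO2-equivalent weights.
    * ``spinup`` -- spu_id -> SpinupConfig.
    """

    growth_curves: dict = field(default_factory=dict)
    allocation_models: dict = field(default_factory=dict)
    root_models: dict = field(default_factory=dict)
    merch_proportion: dict = field(default_factory=dict)
    c_content: dict = field(default_factory=dict)
    turnover: "object" = None
    snag_fall: dict = field(default_factory=dict)
    decay: "object" = None
    matrices: dict = field(default_factory=dict)
    nonarbour_series: dict = field(default_factory=dict)
    soil_defaults: dict = field(default_factory=dict)
    age_groups: dict = field(default_factory=dict)
    harvest_age: dict = field(default_factory=dict)
    emission_factors: "object" = None
    gwp: dict = field(default_factory=dict)
    spinup: dict = field(default_factory=dict)
    leaf_habit: dict = field(default_factory=dict)  # species -> evergreen|deciduous
    transition_years: int = 20
    settings: dict = field(default_factory=dict)

    @property
    def stem_biomass_models(self) -> dict:
        """species -> (a, b) of the volume-to-stemwood power model."""
        return {s: (m.stem_a, m.stem_b) for s, m in self.allocation_models.items()}

    def turnover_class(self, stand: StandRecord) -> str:
        if stand.forest_type in ("bamboo", "economic", "shrub"):
            return stand.forest_type
        if stand.genus_class == "softwood":
            return "coniferous"
        habit = self.leaf_habit.get(stand.species, "evergreen")
        return "broadleaf_deciduous" if habit == "deciduous" else "broadleaf_evergreen"


# C content lint band: the study region's reported species range
C_CONTENT_BAND = (0.439, 0.598)


def validate_parameter_set(p: ParameterSet, stands=None) -> list[str]:
    """Cross-check a parameter set (and optionally an inventory) for dangling
    references, out-of-range rates, and disturbance-matrix row-sum failures.

    Pure function: violations are returned, never raised.
    """
    v: list[str] = []
    for (species, component), c in p.c_content.items():
        if not (0.0 < c < 1.0):
            v.append(f"c_content[{species},{component}]={c} outside (0,1)")
    if p.turnover is not None:
        for (tclass, component), r in p.turnover.rates.items():
            if not (0.0 <= r <= 1.0):
                v.append(f"turnover[{tclass},{component}]={r} outside [0,1]")
    for genus, (rs, rb) in p.snag_fall.items():
        for name, r in (("stem", rs), ("branch", rb)):
            if not (0.0 <= r <= 1.0):
                v.append(f"snag_fall[{genus},{name}]={r} outside [0,1]")
    if p.decay is not None:
        v.extend(p.decay.validate())
    for dtype, m in p.matrices.items():
        v.extend(m.validate())
    for species, (t1, t2, t3, t4) in p.age_groups.items():
        if not (t1 < t2 < t3 < t4):
            v.append(f"age_groups[{species}] thresholds not strictly increasing")
    for species, frac in p.merch_proportion.items():
        if not (0.0 < frac <= 1.0):
            v.append(f"merch_proportion[{species}]={frac} outside (0,1]")
    missing = [c for c in SOIL_CLASSES if c not in p.soil_defaults]
    if missing:
        v.append(f"soil_defaults missing classes: {missing}")
    for cls, d in p.soil_defaults.items():
        if d < 0:
            v.append(f"soil_defaults[{cls}]={d} negative")

    if stands is not None:
        for s in stands:
            if not s.is_forest:
                continue
            if s.forest_type == "arbour":
                if s.classifier_key not in p.growth_curves:
                    v.append(
                        f"stand {s.stand_id}: classifier_key {s.classifier_key!r} "
                        "has no growth curve"
                    )
                if s.species not in p.allocation_models:
                    v.append(f"stand {s.stand_id}: species {s.species!r} missing from allocation_models")
                if s.species not in p.merch_proportion:
                    v.append(f"stand {s.stand_id}: species {s.species!r} missing from merch_proportion")
                if s.species not in p.age_groups:
                    v.append(f"stand {s.stand_id}: species {s.species!r} missing from age_groups")
                if s.species not in p.harvest_age:
                    v.append(f"stand {s.stand_id}: species {s.species!r} missing from harvest_age")
            else:
                if s.species not in p.nonarbour_series:
                    v.append(f"stand {s.stand_id}: species {s.species!r} missing from nonarbour_series")
            for comp in LIVE_POOLS:
                if (s.species, comp) not in p.c_content:
                    v.append(
                        f"stand {s.stand_id}: c_content missing ({s.species!r}, {comp!r})"
                    )
                    break
    return v


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _opt_int(x):
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    return int(x)


def load_inventory(path) -> list[StandRecord]:
    """Read ``inventory.csv`` into StandRecords, enforcing all row invariants."""
    df = pd.read_csv(path, dtype={"stand_id": str, "spu_id": str, "site_quality": str})
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"inventory missing column(s): {missing}")
    stands = []
    problems = []
    for row in df.itertuples(index=False):
        ft = row.forest_type if isinstance(row.forest_type, str) and row.forest_type else None
        s = StandRecord(
            stand_id=str(row.stand_id),
            spu_id=str(row.spu_id),
            species=str(row.species),
            genus_class=str(row.genus_class),
            forest_type=ft,
            origin=str(row.origin),
            land_use=str(row.land_use),
            age=int(row.age),
            area=float(row.area_ha),
            climatic_zone=str(row.climatic_zone),
            site_quality=str(row.site_quality),
            rocky_desertification=str(row.rocky_desertification),
            last_lucc_year=_opt_int(row.last_lucc_year),
        )
        problems.extend(s.validate())
        stands.append(s)
    if problems:
        raise ValidationError("; ".join(problems))
    return stands


def save_inventory(stands, path) -> None:
    rows = []
    for s in stands:
        rows.append(
            {
                "stand_id": s.stand_id,
                "spu_id": s.spu_id,
                "species": s.species,
                "genus_class": s.genus_class,
                "forest_type": s.forest_type or "",
                "origin": s.origin,
                "land_use": s.land_use,
                "age": s.age,
                "area_ha": s.area,
                "climatic_zone": s.climatic_zone,
                "site_quality": s.site_quality,
                "rocky_desertification": s.rocky_desertification,
                "last_lucc_year": "" if s.last_lucc_year is None else s.last_lucc_year,
            }
        )
    pd.DataFrame(rows, columns=INVENTORY_COLUMNS).to_csv(path, index=False)


def load_climate(path) -> dict[str, ClimateSeries]:
    """Read ``climate.csv`` (spu_id, year, mean_annual_temp_c).

    A row with year == 'historic' supplies the spin-up temperature.
    """
    df = pd.read_csv(path, dtype={"spu_id": str, "year": str})
    out: dict[str, ClimateSeries] = {}
    for spu, grp in df.groupby("spu_id"):
        temps = {}
        historic = None
        for row in grp.itertuples(index=False):
            if str(row.year).strip() == "historic":
                historic = float(row.mean_annual_temp_c)
            else:
                temps[int(row.year)] = float(row.mean_annual_temp_c)
        out[str(spu)] = ClimateSeries(str(spu), temps, historic)
    return out


def save_climate(climate: dict, path) -> None:
    rows = []
    for spu, series in climate.items():
        if series.historic_mean is not None:
            rows.append({"spu_id": spu, "year": "historic", "mean_annual_temp_c": series.historic_mean})
        for year in sorted(series.temperatures):
            rows.append({"spu_id": spu, "year": year, "mean_annual_temp_c": series.temperatures[year]})
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt_str(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    return s or None


def load_events(path) -> list[DisturbanceEvent]:
    df = pd.read_csv(path, dtype={"stand_id": str})
    events = []
    problems = []
    for row in df.itertuples(index=False):
        _opt = _opt_str
        e = DisturbanceEvent(
            year=int(row.year),
            stand_id=str(row.stand_id),
            dtype=str(row.dtype),
            post_land_use=_opt(getattr(row, "post_land_use", None)),
            post_species=_opt(getattr(row, "post_species", None)),
            post_origin=_opt(getattr(row, "post_origin", None)),
        )
        problems.extend(e.validate())
        events.append(e)
    if problems:
        raise ValidationError("; ".join(problems))
    return events


def save_events(events, path) -> None:
    rows = [
        {
            "year": e.year,
            "stand_id": e.stand_id,
            "dtype": e.dtype,
            "post_land_use": e.post_land_use or "",
            "post_species": e.post_species or "",
            "post_origin": e.post_origin or "",
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["year", "stand_id", "dtype", "post_land_use", "post_species", "post_origin"]
    ).to_csv(path, index=False)


def _read_csv(path, **kw):
    # round_trip parsing so save/load of a parameter directory is lossless
    return pd.read_csv(path, float_precision="round_trip", **kw)


def load_parameters(param_dir, strict: bool = True) -> ParameterSet:
    """Load a parameter directory (one CSV per table + ``config.yaml``).

    In strict mode a carbon content outside the lint band
    [0.439, 0.598] is an error; in lenient mode it is a warning (the band is
    region-specific).  Rates outside [0, 1] are always errors.
    """
    from .biomass_growth import AllocationModel, GrowthCurve, NonArbourSeries, RootModel
    from .disturbance_engine import DisturbanceMatrix, EmissionFactors
    from .dom_dynamics import DecayParameters, TurnoverTable
    from .initialisation import SpinupConfig

    d = Path(param_dir)
    cfg = {}
    cfg_path = d / "config.yaml"
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text()) or {}

    p = ParameterSet(settings=cfg, transition_years=int(cfg.get("transition_years", 20)))

    gdf = _read_csv(d / "growth_curves.csv")
    for row in gdf.itertuples(index=False):
        coefs = tuple(
            float(getattr(row, f"c{i}"))
            for i in range(1, 7)
            if f"c{i}" in gdf.columns and not pd.isna(getattr(row, f"c{i}"))
        )
        p.growth_curves[row.classifier_key] = GrowthCurve(
            classifier_key=row.classifier_key,
            family=row.family,
            coefficients=coefs,
            max_age=int(row.max_age),
        )

    adf = _read_csv(d / "allocation_models.csv")
    for row in adf.itertuples(index=False):
        p.allocation_models[row.species] = AllocationModel(
            species=row.species,
            stem_a=float(row.stem_a),
            stem_b=float(row.stem_b),
            logit={
                k: (float(getattr(row, f"z0_{k}")), float(getattr(row, f"z1_{k}")))
                for k in ("stemwood", "bark", "branches", "foliage")
            },
        )

    rdf = _read_csv(d / "root_models.csv")
    for row in rdf.itertuples(index=False):
        p.root_models[row.genus_class] = RootModel(
            genus_class=row.genus_class,
            form=row.form,
            a=float(row.a),
            b=float(row.b),
            fine_a=float(row.fine_a),
            fine_b=float(row.fine_b),
            fine_k=float(row.fine_k),
        )

    mdf = _read_csv(d / "merch_proportion.csv")
    for row in mdf.itertuples(index=False):
        frac = float(row.proportion)
        if not (0.0 < frac <= 1.0):
            raise ValidationError(f"merch_proportion[{row.species}]={frac} outside (0,1]")
        p.merch_proportion[row.species] = frac

    cdf = _read_csv(d / "c_content.csv")
    lo, hi = C_CONTENT_BAND
    for row in cdf.itertuples(index=False):
        c = float(row.value)
        if not (0.0 < c < 1.0):
            raise ValidationError(f"c_content[{row.species},{row.component}]={c} outside (0,1)")
        if not (lo <= c <= hi):
            msg = (
                f"c_content[{row.species},{row.component}]={c} outside the regional "
                f"band [{lo}, {hi}]"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg)
        p.c_content[(row.species, row.component)] = c

    tdf = _read_csv(d / "turnover.csv")
    rates = {}
    for row in tdf.itertuples(index=False):
        r = float(row.rate)
        if not (0.0 <= r <= 1.0):
            raise ValidationError(f"turnover[{row.forest_type},{row.component}]={r} outside [0,1]")
        rates[(row.forest_type, row.component)] = r
    p.turnover = TurnoverTable(rates)

    sdf = _read_csv(d / "snag_fall.csv")
    for row in sdf.itertuples(index=False):
        p.snag_fall[row.genus_class] = (float(row.snag_stem_rate), float(row.snag_branch_rate))

    ddf = _read_csv(d / "decay.csv")
    p.decay = DecayParameters.from_frame(
        ddf, slow_mixing_rate=float(cfg.get("slow_mixing_rate", 0.006))
    )

    mat_dir = d / "matrices"
    for f in sorted(mat_dir.glob("*.csv")):
        dtype = f.stem
        p.matrices[dtype] = DisturbanceMatrix.from_frame(dtype, _read_csv(f))

    ndf = _read_csv(d / "nonarbour_series.csv")
    for species, grp in ndf.groupby("species"):
        grp = grp.sort_values("age")
        p.nonarbour_series[species] = NonArbourSeries(
            species=species,
            maturity_age=int(grp["maturity_age"].iloc[0]),
            ages=grp["age"].to_numpy(dtype=float),
            agb_pua=grp["agb_pua"].to_numpy(dtype=float),
            bgb_pua=grp["bgb_pua"].to_numpy(dtype=float),
            alloc=grp[["p_stem", "p_branch", "p_foliage", "p_coarse", "p_fine"]].to_numpy(dtype=float),
        )

    soil = _read_csv(d / "soil_defaults.csv")
    for row in soil.itertuples(index=False):
        p.soil_defaults[row.soil_class] = float(row.bg_slow_mgc_ha)

    agdf = _read_csv(d / "age_groups.csv")
    for row in agdf.itertuples(index=False):
        p.age_groups[row.species] = (float(row.t1), float(row.t2), float(row.t3), float(row.t4))

    hdf = _read_csv(d / "harvest_age.csv")
    for row in hdf.itertuples(index=False):
        p.harvest_age[row.species] = int(row.harvest_age)

    edf = _read_csv(d / "emission_factors.csv")
    erow = edf.iloc[0]
    p.emission_factors = EmissionFactors(
        co2_frac=float(erow["co2_frac"]),
        co_frac=float(erow["co_frac"]),
        ch4_frac=float(erow["ch4_frac"]),
        n2o_per_c=float(erow["n2o_per_c"]),
    )
    p.emission_factors.validate(raise_=True)

    gwpdf = _read_csv(d / "gwp.csv")
    p.gwp = {row.gas: float(row.factor) for row in gwpdf.itertuples(index=False)}

    spdf = _read_csv(d / "spinup.csv", dtype={"spu_id": str})
    for row in spdf.itertuples(index=False):
        p.spinup[str(row.spu_id)] = SpinupConfig(
            return_interval=int(row.return_interval),
            tolerance=float(row.tolerance),
            max_rotations=int(row.max_rotations),
            last_pass_dtype=str(row.last_pass_dtype),
        )

    lh_path = d / "leaf_habit.csv"
    if lh_path.exists():
        lhdf = _read_csv(lh_path)
        p.leaf_habit = {row.species: row.habit for row in lhdf.itertuples(index=False)}

    violations = validate_parameter_set(p)
    if violations:
        raise ValidationError("; ".join(violations))
    return p


def save_parameters(p: ParameterSet, param_dir) -> None:
    """Write a ParameterSet back to a parameter directory (round-trip of
    :func:`load_parameters`)."""
    d = Path(param_dir)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for key, c in p.growth_curves.items():
        row = {"classifier_key": key, "family": c.family, "max_age": c.max_age}
        for i, v in enumerate(c.coefficients, start=1):
            row[f"c{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "growth_curves.csv", index=False, float_format="%.17g")

    rows = []
    for s, m in p.allocation_models.items():
        row = {"species": s, "stem_a": m.stem_a, "stem_b": m.stem_b}
        for k, (z0, z1) in m.logit.items():
            row[f"z0_{k}"] = z0
            row[f"z1_{k}"] = z1
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "allocation_models.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {
                "genus_class": g,
                "form": m.form,
                "a": m.a,
                "b": m.b,
                "fine_a": m.fine_a,
                "fine_b": m.fine_b,
                "fine_k": m.fine_k,
            }
            for g, m in p.root_models.items()
        ]
    ).to_csv(d / "root_models.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [{"species": s, "proportion": f} for s, f in p.merch_proportion.items()]
    ).to_csv(d / "merch_proportion.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [{"species": s, "component": c, "value": v} for (s, c), v in p.c_content.items()]
    ).to_csv(d / "c_content.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"forest_type": t, "component": c, "rate": r}
            for (t, c), r in p.turnover.rates.items()
        ]
    ).to_csv(d / "turnover.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"genus_class": g, "snag_stem_rate": rs, "snag_branch_rate": rb}
            for g, (rs, rb) in p.snag_fall.items()
        ]
    ).to_csv(d / "snag_fall.csv", index=False, float_format="%.17g")

    p.decay.to_frame().to_csv(d / "decay.csv", index=False, float_format="%.17g")

    mat_dir = d / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for dtype, m in p.matrices.items():
        m.to_frame().to_csv(mat_dir / f"{dtype}.csv", index=False, float_format="%.17g")

    rows = []
    for s, series in p.nonarbour_series.items():
        for i, age in enumerate(series.ages):
            rows.append(
                {
                    "species": s,
                    "maturity_age": series.maturity_age,
                    "age": age,
                    "agb_pua": series.agb_pua[i],
                    "bgb_pua": series.bgb_pua[i],
                    "p_stem": series.alloc[i, 0],
                    "p_branch": series.alloc[i, 1],
                    "p_foliage": series.alloc[i, 2],
                    "p_coarse": series.alloc[i, 3],
                    "p_fine": series.alloc[i, 4],
                }
            )
    pd.DataFrame(rows).to_csv(d / "nonarbour_series.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [{"soil_class": c, "bg_slow_mgc_ha": v} for c, v in p.soil_defaults.items()]
    ).to_csv(d / "soil_defaults.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"species": s, "t1": t1, "t2": t2, "t3": t3, "t4": t4}
            for s, (t1, t2, t3, t4) in p.age_groups.items()
        ]
    ).to_csv(d / "age_groups.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [{"species": s, "harvest_age": a} for s, a in p.harvest_age.items()]
    ).to_csv(d / "harvest_age.csv", index=False, float_format="%.17g")

    f = p.emission_factors
    pd.DataFrame(
        [
            {
                "co2_frac": f.co2_frac,
                "co_frac": f.co_frac,
                "ch4_frac": f.ch4_frac,
                "n2o_per_c": f.n2o_per_c,
            }
        ]
    ).to_csv(d / "emission_factors.csv", index=False, float_format="%.17g")

    pd.DataFrame([{"gas": g, "factor": v} for g, v in p.gwp.items()]).to_csv(
        d / "gwp.csv", index=False
    )

    pd.DataFrame(
        [
            {
                "spu_id": spu,
                "return_interval": c.return_interval,
                "tolerance": c.tolerance,
                "max_rotations": c.max_rotations,
                "last_pass_dtype": c.last_pass_dtype,
            }
            for spu, c in p.spinup.items()
        ]
    ).to_csv(d / "spinup.csv", index=False, float_format="%.17g")

    if p.leaf_habit:
        pd.DataFrame(
            [{"species": s, "habit": h} for s, h in p.leaf_habit.items()]
        ).to_csv(d / "leaf_habit.csv", index=False, float_format="%.17g")

    cfg = dict(p.settings)
    cfg["slow_mixing_rate"] = p.decay.slow_mixing_rate
    cfg["transition_years"] = p.transition_years
    (d / "config.yaml").write_text(yaml.safe_dump(cfg))
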