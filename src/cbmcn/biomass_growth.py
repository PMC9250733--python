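"""Live biomass carbon by component and the net annual growth increment.

Arbour stands follow the volume pathway: a stand-classifier-specific
age-to-volume growth curve gives gross volume (m3/ha); a power model turns
volume into stemwood dry biomass; a multinomial-logit model splits total
aboveground biomass into stemwood, bark, branches and foliage; empirical
genus-class equations derive roots from aboveground biomass.  Pool
assignment then depends on the stand's age group: only mature (MF) and
post-mature (PMF) stands carry a merchantable stemwood pool, younger groups
put all stem and bark into "other wood" alongside branches.

Bamboo, economic and shrub stands bypass the volume pathway entirely: an
age -> biomass-per-unit-area series (flat at and after the maturity age) is
allocated to the five components by tabulated age-specific coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    AGE_GROUPS,
    I_COARSE,
    I_FINE,
    I_FOLIAGE,
    I_MERCH,
    I_OTHER,
    LIVE_POOLS,
    N_LIVE,
    LookupFailure,
    ParameterSet,
    PoolVector,
    StandRecord,
)

P_STEM_FLOOR = 1e-6  # below this the stem proportion makes AGB = B_stem/p_stem blow up

AG_COMPONENTS = ("stemwood", "bark", "branches", "foliage")


class DegenerateAllocationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthCurve:
    """Age-to-volume curve for one five-level stand classifier.

    Families:

    * ``richards``  -- V(a) = A (1 - exp(-k a))^c, coefficients (A, k, c)
    * ``logistic``  -- logistic in age, shifted and rescaled so V(0) = 0,
      coefficients (A, b, k)
    * ``korf``      -- V(a) = A exp(-b a^-c), coefficients (A, b, c); V(0) = 0
      in the limit and is returned exactly
    * ``tabulated`` -- piecewise-linear through (age, volume) pairs given as
      flattened coefficients (a1, v1, a2, v2, ...); (0, 0) is implied

    Evaluation beyond ``max_age`` returns the value at ``max_age``.
    """

    classifier_key: str
    family: str
    coefficients: tuple
    max_age: int

    def volume(self, age: float) -> float:
        if age < 0:
            raise ValueError("age must be >= 0")
        a = min(float(age), float(self.max_age))
        if a == 0.0:
            return 0.0
        c = self.coefficients
        if self.family == "richards":
            A, k, shape = c[0], c[1], c[2]
            return A * (1.0 - math.exp(-k * a)) ** shape
        if self.family == "logistic":
            A, b, k = c[0], c[1], c[2]
            f0 = 1.0 / (1.0 + b)
            f = 1.0 / (1.0 + b * math.exp(-k * a))
            return A * (f - f0) / (1.0 - f0)
        if self.family == "korf":
            A, b, shape = c[0], c[1], c[2]
            return A * math.exp(-b * a ** (-shape))
        if self.family == "tabulated":
            ages = np.concatenate(([0.0], np.asarray(c[0::2], dtype=float)))
            vols = np.concatenate(([0.0], np.asarray(c[1::2], dtype=float)))
            return float(np.interp(a, ages, vols))
        raise ValueError(f"unknown growth-curve family {self.family!r}")


def stand_volume(curve: GrowthCurve, age: float) -> float:
    """Gross stand volume (m3/ha) at a given age; clamped at the curve's max age."""
    return curve.volume(age)


# ---------------------------------------------------------------------------
# Volume -> aboveground components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllocationModel:
    """Stemwood power model B_stem = a V^b plus multinomial-logit proportions.

    ``logit`` maps each component k in (stemwood, bark, branches, foliage) to
    (z0, z1) with z_k = z0 + z1 ln(V); proportions are the softmax over the
    four components, so they are positive and sum to one by construction.
    """

    species: str
    stem_a: float
    stem_b: float
    logit: dict

    def proportions(self, volume: float) -> dict:
        lnv = math.log(volume) if volume > 0 else 0.0
        z = np.array([self.logit[k][0] + self.logit[k][1] * lnv for k in AG_COMPONENTS])
        z -= z.max()  # overflow guard; softmax is shift-invariant
        e = np.exp(z)
        p = e / e.sum()
        return dict(zip(AG_COMPONENTS, p))


def aboveground_components(model: AllocationModel, volume: float) -> dict:
    """Component dry biomass (Mg/ha): stemwood, bark, branches, foliage."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    if volume == 0.0:
        return {k: 0.0 for k in AG_COMPONENTS}
    b_stem = model.stem_a * volume**model.stem_b
    p = model.proportions(volume)
    if p["stemwood"] <= P_STEM_FLOOR:
        raise DegenerateAllocationError(
            f"species {model.species!r}: stem proportion {p['stemwood']:.2e} at "
            f"volume {volume} is below the {P_STEM_FLOOR} floor"
        )
    agb = b_stem / p["stemwood"]
    return {k: p[k] * agb for k in AG_COMPONENTS}


# ---------------------------------------------------------------------------
# Aboveground -> belowground
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootModel:
    """Total root biomass from AGB plus a saturating fine-root fraction.

    ``form`` is ``linear`` (roots = a * AGB, the softwood default) or
    ``power`` (roots = a * AGB^b, the hardwood default).  The fine-root
    fraction of total roots is fine_a + fine_b * exp(-fine_k * roots), a
    decreasing function of root mass clamped to [0, 1].
    """

    genus_class: str
    form: str
    a: float
    b: float
    fine_a: float = 0.072
    fine_b: float = 0.354
    fine_k: float = 0.06

    def total_roots(self, agb: float) -> float:
        if agb <= 0.0:
            return 0.0
        if self.form == "linear":
            return self.a * agb
        if self.form == "power":
            return self.a * agb**self.b
        raise ValueError(f"unknown root model form {self.form!r}")

    def fine_fraction(self, roots: float) -> float:
        f = self.fine_a + self.fine_b * math.exp(-self.fine_k * roots)
        return min(1.0, max(0.0, f))


def belowground_components(root_model: RootModel, agb: float, genus_class: str | None = None) -> tuple:
    """(coarse_roots, fine_roots) dry biomass in Mg/ha; coarse + fine = total."""
    if agb < 0:
        raise ValueError("agb must be >= 0")
    roots = root_model.total_roots(agb)
    if roots == 0.0:
        return (0.0, 0.0)
    fine = roots * root_model.fine_fraction(roots)
    return (roots - fine, fine)


# ---------------------------------------------------------------------------
# Age groups and pool assignment
# ---------------------------------------------------------------------------


def age_group(schedule: dict, species: str, age: float) -> str:
    """Map a stand age to YF / MAF / NMF / MF / PMF.

    A boundary age belongs to the older group (a stand that has reached a
    threshold has entered that group).
    """
    try:
        thresholds = schedule[species]
    except KeyError:
        raise LookupFailure(f"species {species!r} missing from age-group schedule") from None
    idx = sum(age >= t for t in thresholds)
    return AGE_GROUPS[idx]


def assign_biomass_pools(components: dict, roots: tuple, group: str, merch_proportion: float) -> PoolVector:
    """Assign component dry biomass (Mg) to the five live pools.

    Mature and post-mature stands put the merchantable portion of stem+bark
    into the merchantable pool and the tops-and-stumps remainder plus all
    branches into other wood; younger stands put all stem, bark and branches
    into other wood.  Total mass is conserved exactly.
    """
    if not (0.0 < merch_proportion <= 1.0):
        raise ValueError("merch_proportion must be in (0, 1]")
    stem_bark = components["stemwood"] + components["bark"]
    out = PoolVector.zeros()
    if group in ("MF", "PMF"):
        out.data[I_MERCH] = merch_proportion * stem_bark
        out.data[I_OTHER] = (1.0 - merch_proportion) * stem_bark + components["branches"]
    else:
        out.data[I_OTHER] = stem_bark + components["branches"]
    out.data[I_FOLIAGE] = components["foliage"]
    out.data[I_COARSE] = roots[0]
    out.data[I_FINE] = roots[1]
    return out


# ---------------------------------------------------------------------------
# Non-arbour pathway
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NonArbourSeries:
    """Tabulated age -> biomass per unit area for bamboo/economic/shrub stands.

    ``ages`` are the tabulated ages (Mg dry matter/ha at each); the series is
    linearly interpolated below the maturity age, held constant at and after
    it, and floored at zero below the first tabulated age.  ``alloc`` holds
    per-age allocation coefficients over (stem, branches, foliage, coarse
    roots, fine roots); rows are renormalised to sum to one at evaluation.
    """

    species: str
    maturity_age: int
    ages: np.ndarray
    agb_pua: np.ndarray
    bgb_pua: np.ndarray
    alloc: np.ndarray

    def biomass_pua(self, age: float) -> tuple:
        if len(self.ages) == 0:
            raise ValueError(f"empty non-arbour series for {self.species!r}")
        a = min(float(age), float(self.maturity_age))
        if a < self.ages[0]:
            return (0.0, 0.0)
        agb = float(np.interp(a, self.ages, self.agb_pua))
        bgb = float(np.interp(a, self.ages, self.bgb_pua))
        return (agb, bgb)

    def allocation(self, age: float) -> np.ndarray:
        a = min(float(age), float(self.maturity_age))
        coefs = np.array(
            [np.interp(a, self.ages, self.alloc[:, j]) for j in range(5)]
        )
        total = coefs.sum()
        if total <= 0:
            raise ValueError(f"non-arbour allocation for {self.species!r} sums to 0")
        return coefs / total


def nonarbour_biomass(
    series: NonArbourSeries, age: float, area: float, forest_type: str = "shrub"
) -> PoolVector:
    """Live-pool dry biomass (Mg per stand) for a bamboo/economic/shrub stand.

    Stem biomass maps to the merchantable pool only for bamboo at or after
    maturity (bamboo is harvested as culms); otherwise stems join other wood.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if area <= 0:
        raise ValueError("area must be > 0")
    agb, bgb = series.biomass_pua(age)
    total = (agb + bgb) * area
    out = PoolVector.zeros()
    if total == 0.0:
        return out
    p_stem, p_branch, p_foliage, p_coarse, p_fine = series.allocation(age)
    # Rescale so AG components exhaust AGB and BG components exhaust BGB.
    ag_w = p_stem + p_branch + p_foliage
    bg_w = p_coarse + p_fine
    stem = agb * area * (p_stem / ag_w) if ag_w > 0 else 0.0
    branch = agb * area * (p_branch / ag_w) if ag_w > 0 else 0.0
    fol = agb * area * (p_foliage / ag_w) if ag_w > 0 else 0.0
    coarse = bgb * area * (p_coarse / bg_w) if bg_w > 0 else 0.0
    fine = bgb * area * (p_fine / bg_w) if bg_w > 0 else 0.0
    if forest_type == "bamboo" and age >= series.maturity_age:
        out.data[I_MERCH] = stem
    else:
        out.data[I_OTHER] = stem
    out.data[I_OTHER] += branch
    out.data[I_FOLIAGE] = fol
    out.data[I_COARSE] = coarse
    out.data[I_FINE] = fine
    return out


# ---------------------------------------------------------------------------
# Carbon conversion and the full pathway
# ---------------------------------------------------------------------------


def biomass_to_carbon(live: PoolVector, c_content: dict, species: str) -> PoolVector:
    """Multiply each live pool by its species-and-component carbon content."""
    out = live.copy()
    for i, pool in enumerate(LIVE_POOLS):
        try:
            c = c_content[(species, pool)]
        except KeyError:
            raise LookupFailure(f"c_content missing ({species!r}, {pool!r})") from None
        out.data[i] = live.data[i] * c
    return out


def live_carbon(stand: StandRecord, p: ParameterSet, age: float) -> np.ndarray:
    """Live-pool carbon (Mg C, whole stand) at a given age via the full pathway."""
    if stand.forest_type == "arbour":
        try:
            curve = p.growth_curves[stand.classifier_key]
        except KeyError:
            raise LookupFailure(
                f"classifier_key {stand.classifier_key!r} has no growth curve"
            ) from None
        model = p.allocation_models[stand.species]
        volume = stand_volume(curve, age)
        comps = aboveground_components(model, volume)
        agb = sum(comps.values())
        roots = belowground_components(p.root_models[stand.genus_class], agb)
        group = age_group(p.age_groups, stand.species, age)
        dry = assign_biomass_pools(comps, roots, group, p.merch_proportion[stand.species])
        dry.data[:N_LIVE] *= stand.area
    else:
        series = p.nonarbour_series[stand.species]
        dry = nonarbour_biomass(series, age, stand.area, stand.forest_type)
    carbon = biomass_to_carbon(dry, p.c_content, stand.species)
    return carbon.data[:N_LIVE].copy()


_TRAJ_CACHE: dict = {}


def live_carbon_trajectory(stand: StandRecord, p: ParameterSet, max_age: int) -> np.ndarray:
    """Per-hectare live-carbon trajectory (ages 0..max_age, shape (max_age+1, 5)).

    Cached per (parameter set, pathway key); multiply by stand area to get
    whole-stand carbon.  The cache key includes everything the pathway reads.
    """
    key = (
        id(p),
        stand.classifier_key if stand.forest_type == "arbour" else stand.species,
        stand.forest_type,
        stand.genus_class,
    )
    cached = _TRAJ_CACHE.get(key)
    if cached is not None and cached.shape[0] > max_age:
        return cached
    unit = stand.with_(area=1.0)
    traj = np.empty((max_age + 1, N_LIVE))
    for a in range(max_age + 1):
        traj[a] = live_carbon(unit, p, a)
    _TRAJ_CACHE[key] = traj
    return traj


def clear_trajectory_cache() -> None:
    _TRAJ_CACHE.clear()


def net_growth_increment(stand: StandRecord, p: ParameterSet) -> PoolVector:
    """Net annual growth: carbon at age+1 minus at age, per pool, floored at 0.

    The floor means declining curve segments contribute no uptake rather than
    a biomass loss (the model has no decline-routing process).
    """
    if not stand.is_forest:
        raise ValueError(f"stand {stand.stand_id} is not forested")
    now = live_carbon(stand, p, stand.age)
    nxt = live_carbon(stand, p, stand.age + 1)
    delta = np.maximum(nxt - now, 0.0)
    out = PoolVector.zeros()
    out.data[:N_LIVE] = delta
    return out
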