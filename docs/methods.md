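# Methods

## Scope and state

The simulator tracks carbon (Mg C) per stand in 14 pools — five live
(merchantable stemwood + bark, other wood + bark, foliage, coarse roots,
fine roots) and nine dead-organic-matter (DOM) pools (stem snags, branch
snags, medium woody debris, above-ground very-fast/fast/slow, below-ground
very-fast/fast/slow) — plus two cumulative sinks (atmosphere, forest
products). Snag pools carry the stand's genus class (softwood/hardwood lead
species), so across the two genus classes the layout corresponds to the
conventional eleven-DOM-pool structure of CBM-CFS3-family models. The model
is not spatially explicit: stands are rows with spatially referenced IDs
(spatial unit, climatic zone, site quality, rocky-desertification class),
and there is no stand-to-stand coupling — the joint run of N stands equals
the union of N single-stand runs, which the tests assert.

Mixed stands carry the single genus class of their lead species; the
inventory schema assigns one dominant species per stand, and no biomass is
split across parameter sets.

## Growth pathways

**Arbour stands** follow volume → biomass → components → pools:

* Growth curves are resolved by a five-level classifier (species, climatic
  zone, site-quality degree, origin, rocky-desertification type). Four
  families are supported — Richards `A(1−e^(−ka))^c`, a logistic rescaled to
  force V(0)=0, Korf `A·e^(−b·a^(−c))`, and tabulated with linear
  interpolation. Evaluation is clamped at `max_age`. Coefficients always
  come from the parameter directory; the package fits nothing.
* Stemwood dry biomass is the power model `B_stem = a·V^b`. Component
  proportions over {stemwood, bark, branches, foliage} are a softmax of
  `z_k = z0_k + z1_k·ln V`; a full four-component softmax is used rather
  than a three-versus-reference logit (mathematically equivalent given
  coefficients in that basis; parameter tables are encoded accordingly).
  Total AGB is `B_stem / p_stem`, with a floor of 1e−6 on `p_stem` below
  which a degenerate-allocation error is raised.
* Roots: softwood total roots are linear in AGB (default 0.222·AGB),
  hardwood follow a power law (default 1.576·AGB^0.615); the fine-root
  fraction is the saturating, decreasing `0.072 + 0.354·e^(−0.06·roots)`.
  Both functional forms and coefficients are configurable per genus class.
* Pool assignment is age-group based. The inventory's five maturity groups
  (young YF, middle-aged MAF, near-mature NMF, mature MF, post-mature PMF,
  with per-species thresholds; a boundary age belongs to the older group)
  replace the diameter-class stand components of the original algorithm:
  only MF/PMF stands put `merch_proportion` of stem + bark into the
  merchantable pool (remainder plus branches into other wood); younger
  groups put all stem, bark and branches into other wood. The merchantable
  versus tops-and-stumps split is a per-species scalar in (0, 1] — the
  simplest faithful parameterisation; a volume-dependent rule can be
  emulated by species-level values.

**Bamboo, economic and shrub stands** have no usable stand volume; they use
tabulated age → biomass-per-unit-area (AGB, BGB in Mg dry matter/ha) series
with per-age allocation coefficients over stem/branches/foliage/coarse/fine.
The series interpolates linearly between tabulated ages, is constant at and
after the maturity age, and is zero below the first tabulated age. AG
coefficients are rescaled to exhaust the tabulated AGB and BG coefficients
the tabulated BGB, so both tables are honoured and mass is conserved. Stem
biomass maps to the merchantable pool only for bamboo at or after maturity
(bamboo is harvested as culms); otherwise stems join other wood.

Dry matter converts to carbon with species-and-component contents
(g C/g dry matter); a loader lint band of [0.439, 0.598] reflects the
reference region's reported species range and is an error in strict mode,
a warning in lenient mode.

**Net annual increment** is the pathway difference between consecutive ages,
floored at zero per pool: declining curve segments contribute no uptake
rather than a biomass loss, since the model has no decline-routing process.
Note a bookkeeping consequence of the step structure (growth adds curve
deltas; turnover subtracts from live pools): fast-turnover pools such as
foliage equilibrate below the static curve value. This is the model's
convention, consistent throughout the ledger and conservation identities.

## Turnover, decay, mixing

Turnover rates are per (turnover class × component); classes are coniferous,
evergreen/deciduous broadleaf, bamboo, economic, shrub, with the three
non-arbour classes defaulting to the evergreen-broadleaf row unless
overridden. Routing (stem → stem snag, other wood → branch snag, foliage →
AG very fast, fine roots 50/50 AG/BG very fast, coarse roots 50/50 AG/BG
fast; snag fall to medium debris and AG fast) follows the standard
CBM-CFS3 scheme and is configurable per source pool.

Decay is first-order with a Q10 temperature modifier,
`rate = min(1, base_rate · q10^((T − t_ref)/10))`, using the spatial unit's
mean annual temperature. The cap at 1 preserves non-negativity at any
temperature. A fraction `p_atm` of decayed carbon goes to the atmosphere;
the remainder stabilises into the matching slow pool. Slow pools have no
further stabilisation target: with a configured `p_atm < 1` only the emitted
share leaves (they effectively decay at `p_atm · rate`); shipped defaults
set their `p_atm = 1`. A fixed annual fraction (default 0.006 yr⁻¹) of AG
slow mixes into BG slow. Within a year the order is turnover → snag fall →
decay → mixing. Both steps conserve carbon exactly (asserted to 1e−12
relative by property tests over random pools and rates).

Shipped decay constants (base rates 0.0033–0.5 yr⁻¹ at t_ref 10 °C, Q10 1
for BG slow, 2–2.65 elsewhere, p_atm 0.815–1.0) are reconstructions from the
CBM-CFS3 literature: the study's own decomposition table is not published,
so these are defaults to be replaced by users with local values.

## Disturbances and greenhouse gases

Nine event types are recognised; the transition classifier implements the
generation rules exactly (non-forest → forest by origin → AF/NE; forest →
cropland/built-up/grassland/water/bare → DFA/DFB/FCG/FCW/FDB; forest →
forest with an age reset, split by the species harvest age → HL/RL). The
age-reset detection uses current age ≤ 1, since planting year 0 versus 1 is
not distinguishable in reconstructed histories. DFA defaults to dryland
cropland (configurable): the rules do not specify the cropland subclass.

A disturbance matrix gives, per source pool, the proportions routed to every
pool, the atmosphere and the products sector; rows sum to 1, application is
simultaneous against pre-disturbance stocks (proportions are defined on
pre-event state), and carbon is conserved exactly. Rows flagged `is_burning`
contribute their atmosphere flux to "burned carbon", which is speciated as
CO₂/CO/CH₄ by carbon fractions (default 0.90/0.09/0.01, converted by molar
ratios 44/12, 28/12, 16/12) plus N₂O at `n2o_per_c` (default 5.7e−4 Mg/Mg);
all non-combustion emissions are pure CO₂, so AF/NE/FCG/FCW/FDB produce no
trace gases. CO₂-equivalents use 100-year GWPs CO₂ = 1, CH₄ = 21, N₂O = 310,
CO = 0 — the set consistent with the reference case's printed totals.
The shipped matrices are reconstructions (the study's modified matrices are
not published): harvest sends 85% of merchantable stemwood to products,
regeneration logging burns more and salvages less, deforestation for
agriculture burns heavily and consumes surface litter, the conversion types
without burning move carbon to DOM and products. All are plain CSVs and
fully replaceable.

## Initialisation

Forest spin-up repeats {grow from age 0 for the historic disturbance-return
interval with full annual dynamics at the historic temperature; apply the
stand-replacing FIRE matrix} until the BG slow pool changes by less than the
tolerance between successive rotation ends (default 0.1%, max 200
rotations), then applies the last-pass clear-cut matrix and grows to the
inventory age. Convergence is tested on BG slow only — the slowest pool —
and the procedure is fully deterministic. Note the stopping rule bounds the
successive difference, not the distance to the fixed point; with contraction
`q = (1−k)^R` per rotation the residual error is ≲ tolerance·q/(1−q), which
the tests use as their bound. The spin-up's own atmosphere/products sinks
are zeroed at hand-over: initialisation is pre-simulation history. The
historic temperature defaults to the climate series' earliest decade's mean
unless a `historic` row is supplied; spin-up uses the stand's own inventory
species and curve (no historic-species table exists).

Non-forest land starts at "vegetation + land-use" class BG-slow defaults
(seven classes: paddy, dryland, grassland, wetland, inland water, built-up,
bare). After a land-use change the stock moves **linearly** from the old to
the new class default over 20 years and then holds — linear being the
simplest shape consistent with standard 20-year default-transition practice;
the length is configurable. A stand afforested inside the window freezes the
transition value at the planting year and switches to forest dynamics from
that year. During a simulation, a forest → non-forest conversion starts the
same transition from the stand's actual post-disturbance BG slow stock
toward the target class default, with the annual delta routed to or from the
atmosphere and recorded in the ledger so mass balance closes.

## Orchestration and audit

The annual step order is growth → turnover → decay → disturbance, following
the customised model's narrative order; the original model disturbs before
growth, and a `disturbance_first` flag switches to that convention.
Events come from the event schedule; the classifier is also exposed for
deriving events from consecutive inventory snapshots. Missing climate years
are errors, never interpolated. A start of 1990 and end of 2016 yields 27
annual states and 26 transitions; change statistics divide by 26.

Every transfer lands in a flux ledger keyed (year, stand, process, source,
target); flows from "atmosphere" are uptake. The audit recomputes, for every
stand-year, `Δpools − (uptake − atmosphere − products)` relative to the
stock; completed runs sit at numerical round-off (~1e−16) and the acceptance
threshold is 1e−9.

## Reporting

Model pools aggregate to the five IPCC GPG pools: AG biomass (merchantable,
other wood, foliage), BG biomass (roots), dead wood (snags, medium debris,
and BG fast — dead coarse roots), litter (AG very-fast/fast/slow), soil (BG
very-fast/slow). Stocks are Tg C; densities divide by the year's forest
area. Trend slopes are ordinary least squares of stock on calendar year with
a two-sided t-test (at least three years required). Disturbance summaries
derive per-type area, biomass/DOM stock change, atmosphere and products
expenditure from the ledger; the identities total = biomass + DOM and
expenditure = atmosphere + products hold exactly by construction. Derived
shares are reported raw plus a "printed" rendering (per-type shares to one
decimal, aggregate shares to integers, annual rates to two decimals); zero
denominators yield NaN markers rather than exceptions.

## Synthetic data

The real survey (three million stands) and most coefficient tables are not
public, so the generator emulates them: forest-type composition fixed at the
reference province's 2016 survey mix (39.7% coniferous, 27.6% broad-leaved,
25.2% shrub, 6.0% economic, 1.5% bamboo), a six-species arbour palette plus
moso bamboo / economic / shrub classes, lognormal stand areas (a few ha),
uniform ages, four spatial units with stationary temperatures around a
13–17 °C base, and Richards curves with asymptotes 50–400 m³/ha. Carbon
contents are drawn within the published 0.439–0.598 range and turnover rates
within 0.017–0.952; bamboo matures at 6 years, economic and shrub stands at
8. Event schedules respect the classification rules by construction (harvest
only at or beyond harvest age judged on the prior year's age, at most one
event per stand) and round-trip through the classifier, which is tested.

What the generator does **not** emulate: the spatial structure and true age
and area distributions of the survey, climate trends and interannual spatial
correlation, species-specific allometry fitted to data, and the real
disturbance-rate history. Passing tests therefore demonstrate the machinery
(conservation, classification, convergence, reporting arithmetic), not
calibrated provincial magnitudes: synthetic landscapes equilibrate at lower
carbon density than the reference province because the reconstructed decay
and growth parameters are deliberately generic.

## Numerical choices and limitations

* Matrix rows validated to 1e−9; allocation closure to 1e−9; conservation
  asserted to 1e−12 relative; mass-balance acceptance at 1e−9.
* Applied decay rates capped at 1; negative growth increments floored at 0;
  softmax shift-normalised against overflow.
* Parameter CSVs are written with 17 significant digits and read with
  round-trip float parsing, so save → load is lossless.
* Precipitation is read nowhere: only the temperature effect on decay is
  modelled. Wildfire, insect, wind and other natural disturbances, thinning
  and fertilisation are out of scope, as are post-disturbance dynamics
  beyond the standard annual cycle, karst inorganic carbon, CO₂
  fertilisation and nitrogen deposition.
* Simulation sizes used by the shipped checks: the acceptance run uses
  1000 stands × 27 years (spin-up included; well under a minute of CPU), the
  unit suite uses 25–40-stand runs. These sizes are the package's own test
  design; the machinery scales linearly in stands × years.
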