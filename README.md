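# cbmcn

A stand-level, annual-timestep forest carbon budget simulator implementing
CBM-CFS3-style pool dynamics customised for Chinese planning-and-design
forest inventories, with Guizhou's subtropical karst forests as the
reference case.

## Who this is for

Forest carbon accountants and ecosystem modellers who have stand-wise
inventory tables (dominant species, age, area, land use, origin, site
classifiers), per-region temperature series and a land-use-change /
management event history, and who want full carbon bookkeeping — biomass,
dead organic matter (DOM), soil, atmosphere and harvested products — with
per-transfer auditability.

## The model

Carbon per stand lives in five biomass pools (merchantable stemwood + bark,
other wood + bark, foliage, coarse roots, fine roots), nine DOM pools (stem
and branch snags, medium woody debris, above/belowground very-fast, fast and
slow pools), and two cumulative sinks (atmosphere, forest products). Each
simulated year applies, in order:

1. **Growth.** For arbour stands, a five-level-classifier growth curve gives
   stand volume V(age) (m³/ha); a power model B_stem = a·V^b gives stemwood
   dry biomass; a multinomial logit p_k ∝ exp(z0_k + z1_k ln V) over
   {stemwood, bark, branches, foliage} expands it to total aboveground
   biomass; genus-class equations (softwood: roots = 0.222·AGB; hardwood:
   roots = 1.576·AGB^0.615, fine fraction 0.072 + 0.354·e^(−0.06·roots))
   give belowground biomass. Pool assignment depends on the stand age group:
   only mature (MF) and post-mature (PMF) stands carry merchantable
   stemwood; younger groups (YF/MAF/NMF) put all stem + bark into other
   wood. Bamboo, economic and shrub stands instead follow a tabulated
   age → biomass-per-unit-area series that is flat at and after maturity.
   The net annual increment is the carbon difference of this pathway between
   consecutive ages, floored at zero per pool.
2. **Turnover.** Each live pool sheds a fixed annual fraction into its DOM
   targets (stem → stem snags, other wood → branch snags, foliage → AG
   very-fast, roots split 50/50 between AG and BG fast/very-fast); snags
   fall into medium debris and AG fast.
3. **Decay.** Every DOM pool decays at base_rate · q10^((T − t_ref)/10),
   capped at 1; a fraction p_atm of decayed carbon is emitted, the rest
   stabilises into the AG or BG slow pool; AG slow mixes into BG slow at a
   fixed rate.
4. **Disturbance.** Nine event types (afforestation AF, natural expansion
   NE, regeneration logging RL, harvest logging HL, deforestation for
   agriculture DFA / built-up DFB, conversion to grassland FCG / water FCW /
   bare land FDB) each carry a proportion matrix routing every source pool
   to pools, atmosphere and products. Burning rows speciate into CO₂/CO/CH₄
   (by carbon fraction, molar-converted) plus N₂O, aggregated to CO₂e by
   global-warming potentials.

Forest stands are initialised by a deterministic spin-up (grow one
disturbance-return interval, apply a stand-replacing fire matrix, repeat
until the BG slow pool converges; end with a clear-cut and regrowth to the
inventory age). Non-forest land starts at vegetation + land-use class soil
defaults and moves linearly to the new class default over 20 years after a
land-use change; afforestation freezes that transition and hands over to
forest dynamics.

Every transfer is recorded in a flux ledger, so for each stand-year
`Δpools = uptake − atmosphere − products` is auditable (it holds to
~1e−16 relative in practice).

## Worked example

The survey data behind the reference case are not public, so the package
ships a seeded synthetic generator that emulates the inventory schema and
published parameter ranges:

```
$ cbmcn synth --seed 5 --n-stands 30 --out land
wrote synthetic landscape (30 stands) to land

$ cbmcn run --config land/config.yaml --out runout
simulated 30 stands over 27 annual states
max mass-balance residual: 4.516e-16

$ cbmcn report --pools runout/annual_pools.csv --ledger runout/ledger.csv \
    --gases runout/gases.csv --events runout/events_applied.csv --out rep
wrote reports to rep
```

`runout/annual_pools.csv` holds one row per stand per year (1990–2016 gives
27 annual states) with all 14 pools plus the cumulative sinks;
`runout/ledger.csv` holds every transfer. The report step aggregates pools
into the five IPCC Good Practice Guidance pools (AG/BG biomass, dead wood,
litter, soil), computes ordinary-least-squares stock trends, per-disturbance
summaries and greenhouse-gas totals. The "max mass-balance residual" line is
the largest stand-year violation of the uptake − emission − products
identity; a correct run prints a value at numerical round-off (~1e−16).

The same machinery is usable as a library:

```python
from cbmcn import (LandscapeSpec, generate_landscape, generate_parameters,
                   RunConfig, run_prepared, check_mass_balance)

stands, climate, events = generate_landscape(LandscapeSpec(seed=1, n_stands=1000))
params = generate_parameters(1)
cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2016)
annual, ledger = run_prepared(stands, params, climate, events, cfg)
print(check_mass_balance(ledger, annual))   # 6.26e-16
```

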