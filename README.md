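# canopyflux

Leaf-to-canopy upscaling of photosynthesis, transpiration and water-use
efficiency for 3D fruit-tree canopies.

Orchard trees assembled from different scion cultivars and interstocks
differ both in **architecture** (how leaves are distributed in space) and
in **leaf function** (photosynthetic capacity, stomatal behaviour, the
nitrogen–light gradient). Whole-canopy carbon gain and water use emerge
from both, and field measurements alone cannot separate their
contributions. `canopyflux` does this *in silico*: it reconstructs
leaf-level 3D canopy mock-ups from digitized shoot skeletons and
allometry, transfers radiation through a voxel turbid medium, couples
leaf biochemistry and stomatal conductance in every voxel, integrates to
daily canopy fluxes, and runs a scenario-switching design that crosses
each treatment's canopy with every treatment's leaf physiology.

The package is aimed at plant ecophysiologists and functional–structural
plant modellers.

## Core models

- **Allometry and reconstruction** — shoot leaf area and leaf count
  linear in shoot length; single-leaf area `LA = a·LL²`; leaves as planar
  hexagons calibrated to the allometric area, spaced at the mean
  internode, azimuths advancing 144° (2/5 phyllotaxy), elevation/rolling
  sampled from field histograms. `LAI = leaf area / tree spacing`.
- **Radiation** — voxel leaf area density; Beer–Lambert extinction
  `exp(−G·LAD·path)` along traced rays, with the G-function integrated
  over the leaf-angle distribution; 46-sector diffuse sky; clearness-index
  direct/diffuse partitioning of measured PPFD; no scattering, so
  intercepted + transmitted = incident exactly.
- **Leaf gas exchange** — Farquhar–von Caemmerer–Berry photosynthesis
  `A = min(Wc, Wj) − Rd`; Jarvis stomatal conductance
  `g_s = g_smax·f(PPFD)·f(T)·f(VPD)` with a plateau-then-decline VPD
  response; coupling through `A(C_i) = (g_s/1.6)(C_a − C_i)` at
  `C_a = 380 µmol mol⁻¹`; optional leaf energy balance. Within-canopy
  parameter heterogeneity follows `N_a = f(PPFD_d)` and
  `V_cmax, J_max, R_d, g_smax = f(N_a)`.
- **Canopy integration** — per 30-min step, sunlit/shaded leaf classes
  per voxel; daily `A_c = Σ A_h·1800·10⁻³` (mmol m⁻² d⁻¹), `E_c`
  likewise (mol m⁻² d⁻¹), `WUE_c = A_c/E_c`; days classed sunny
  (PPFD_d > 45 mol m⁻² d⁻¹) or cloudy (< 15).
- **Statistics** — ANCOVA-style slope/intercept comparison, sequential
  two-way variance partitioning, RMSE/RRMSE validation with accuracy
  classes.

A synthetic-data module generates every input — shoot skeletons, weather,
A–Ci and stomatal response curves — from known ground truth, so every
fitting and upscaling stage is validated by parameter recovery. See
`docs/methods.md` for assumptions and design choices.

## Worked example

```python
from canopyflux.leaf import JarvisParams, LeafFunctionSet
from canopyflux.reconstruction import AngleDistribution, assemble_canopy, compute_lai
from canopyflux.simulate import run_season
from canopyflux.synthetic import default_allometry, gen_shoot_skeleton, gen_weather

shoots = gen_shoot_skeleton({"counts": {"long": 25, "short": 40}}, seed=2)
scene = assemble_canopy(shoots, default_allometry(),
                        AngleDistribution.planophile(), seed=2)
print(f"LAI = {compute_lai(scene):.2f}")

funcs = LeafFunctionSet(
    treatment="VD Fuji", na_vs_ppfdd=(0.025, 1.2),
    vcmax_vs_na=(30.0, 5.0), jmax_vs_na=(55.0, 20.0),
    rd_vs_na=(-0.3, 2.0), gsmax_vs_na=(0.15, 0.05),
    jarvis=JarvisParams(g_smax=0.4, vpd0=1.6, vpd_slope=0.35))

weather = gen_weather(2, day_mix=(0.5, 0.5, 0.0), seed=3)
result = run_season(scene, funcs, weather)
print(result.days[["doy", "A_c", "E_c", "WUE_c", "day_class"]].round(2))
```

Output:

```
LAI = 0.16
   doy     A_c     E_c  WUE_c day_class
0  190  706.17  251.84   2.80     sunny
1  191  254.15   98.97   2.57    cloudy
```

One sunny and one cloudy synthetic day: daily canopy photosynthesis
`A_c` (mmol CO₂ m⁻² leaf d⁻¹) and transpiration `E_c` (mol H₂O m⁻² leaf
d⁻¹) drop on the cloudy day while water-use efficiency `WUE_c`
(mmol CO₂ per mol H₂O) stays near 3 — the canopy assimilates ~3 mmol of
CO₂ per mol of water transpired under both skies.

A command-line interface wraps the same functions:

```bash
canopyflux generate --what weather --seed 3 --n-days 4 --out data/
canopyflux fit --what aci --obs data/aci.csv
canopyflux simulate --shoots data/shoots.csv --funcs funcs.json \
    --weather data/weather.csv --out days.csv
```

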