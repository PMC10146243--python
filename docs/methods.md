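# Methods

`canopyflux` upscales leaf gas exchange to whole-canopy daily carbon gain,
water loss and water-use efficiency for 3D fruit-tree canopies, and
partitions treatment differences into architecture (leaf distribution) and
physiology (leaf function) contributions by a scenario-switching design.
This note records the models, the choices made where the design was open,
and what the synthetic test conditions do and do not demonstrate.

## Canopy reconstruction

A canopy is a set of leafy shoots, each a 3D segment (proximal and distal
endpoints). Shoots longer than 5 cm are classed "long", shorter ones
"short"; bourse shoots keep their own label but are dressed with leaves by
the same rules applied to their own length. Five allometric relations
drive the dressing: shoot leaf area and leaf count are linear in shoot
length (SLA = a·SL + b, SLN likewise), single-leaf area is quadratic in
leaf length (LA = a_LA·LL²), and leaf width and petiole length are linear
in LL. Leaf count is rounded to the nearest integer with a floor of one
(every shoot bears at least one leaf); a negative predicted SLA is clamped
to zero. Both conventions are ours — the source relations are silent about
integer counts and out-of-range extrapolation — and are chosen as the
weakest physically valid constraints.

Each leaf is a planar hexagon: length LL along the midrib, maximum width
LW, shoulder vertices placed so the polygon area equals a_LA·LL² (when
the width constraint makes that infeasible the half-width is adjusted,
keeping the area identity exact, since downstream radiation depends on
area, not outline). Leaves sit at evenly spaced insertion points (mean
internode = SL/SLN), azimuths advance 144° per node (2/5 phyllotaxy, first
azimuth uniform random per shoot to avoid artificial cross-shoot
alignment), and elevation/rolling angles are drawn from per-shoot-type
histograms (default bin width 10°). Petiole, midrib and shoot axis share
the vertical plane through the leaf azimuth.

Coordinates: z up, azimuth clockwise from North, elevation from the
horizontal. LAI = total leaf area / (row × inter-row spacing), default
spacing 2.0 m × 3.5 m.

## Radiation

The scene is voxelized (default edge 0.3 m; leaves assigned by centroid,
with an area-splitting option) into a turbid medium with leaf area density
LAD per voxel. Attenuation along any ray is Beer–Lambert with extinction
G·LAD, where the G-function is the mean projection of unit leaf area
toward the beam, evaluated by averaging |n·s| over a sample of lamina
normals drawn from the leaf-angle distribution. Rays are traced with
Amanatides–Woo voxel traversal from a supersampled entry plane; scattering
is neglected for PPFD (leaf absorptance 0.85 applied to intercepted flux),
which makes energy conservation — intercepted + transmitted = incident —
exact per direction and step and is verified against an independent
Monte-Carlo photon-tracking (null-collision) oracle.

The diffuse sky uses a 46-sector ring ("turtle"-style) discretization with
isotropic-radiance (uniform overcast) weights; the per-voxel diffuse
interception pattern is precomputed once per grid and scaled by each
step's diffuse irradiance. The direct beam follows solar position from
standard declination/hour-angle formulas (site latitude configurable;
the default of 34.5° N suits a mid-latitude temperate orchard). Total PPFD is split into direct and diffuse by an hourly
clearness-index piecewise model (fully diffuse below kt = 0.22, monotone
decline to a solar-elevation-dependent clear-sky floor); NIR is taken
equal to PAR in energy and split in the same ratio; atmospheric longwave
uses the Brutsaert clear-sky emissivity increased toward unity with
cloudiness inferred from the diffuse fraction. The sunlit leaf-area
fraction per voxel is the flux-weighted mean beam transmittance reaching
that voxel.

## Leaf gas exchange

Photosynthesis is the Farquhar–von Caemmerer–Berry model: A = min(Wc, Wj)
− Rd, with electron transport from a non-rectangular hyperbola (θ = 0.9,
α = 0.3). Temperature responses use a single named Arrhenius constant set
(`BERNACCHI_2001`), swappable via configuration; V_cmax, J_max and R_d are
parameterized at 25 °C, so fits at any measurement temperature return
25 °C values directly through the same constant set.

Stomatal conductance is the Jarvis multiplicative model, independent of A:
g_s = g_smax · f(PPFD) · f(T) · f(VPD), each factor in [0, 1]. f(PPFD) is
a saturating hyperbola normalized to 1 at 1500 µmol m⁻² s⁻¹; f(T) a
symmetric optimum curve 1 − ((T − T_opt)/breadth)²; f(VPD) a plateau at 1
up to a threshold VPD₀ then a linear decline. These are the simplest
shapes consistent with the reported response forms (monotone saturating
light response, temperature optimum, threshold-then-decline VPD
response).

The coupling closes the diffusion identity A(C_i) = (g_s/1.6)(C_a − C_i)
(C_a = 380 µmol mol⁻¹) by bracketed root finding (tolerance 10⁻⁴
µmol mol⁻¹). In darkness stomata close (f(PPFD) = 0) and the leaf returns
A = −Rd with zero transpiration; with nearly closed stomata the bracket
widens above C_a, where respiratory efflux balances diffusion.
Transpiration is E = g_s·VPD/P_atm. Leaf temperature equals air
temperature by default; an optional energy balance solves the budget
(absorbed radiation = thermal emission + sensible + latent heat, with
boundary-layer conductance 0.147·√(u/d), leaf dimension 0.08 m) and then
evaluates the surface VPD at leaf temperature.

The canopy nitrogen gradient enters through five linear maps: N_a from
daily cumulated light PPFD_d, then V_cmax25, J_max25, R_d25 and g_smax
from N_a (R_d's slope is negative), all floored at a small positive
value. Each voxel's PPFD_d is computed once from a clear-sky reference
day at the start of the simulated window and held static — leaf nitrogen
acclimates slowly relative to the simulated season.

## Fitting

A–Ci curves are fit by multistart (≥ 5 starts) bounded nonlinear least
squares on the forward model; R_d is co-estimated unless a pre-dawn
measured value is supplied. The duplicated 400 µmol mol⁻¹ chamber step of
the 12-step measurement protocol is retained as two observations. The VPD
threshold is fit by profiling the breakpoint of the continuous
plateau/decline model over a dense candidate grid with the decline slope
in closed form, then refining by bounded 1-D minimization; the fit is
declared unidentifiable when either segment holds fewer than two points
or no decline is evident. g_smax applies the optimal-window filter
(800 ≤ PPFD ≤ 1500, 20 ≤ T ≤ 30 °C, 1.4 ≤ VPD ≤ 2 kPa, C_a = 380) and by
default averages values strictly above the 90th percentile of the
filtered set (`gsmax_rule="p90"` returns the percentile itself; the
verbal rule is ambiguous between the two readings).

## Simulation and scenarios

Per 30-min step each occupied voxel is split into a sunlit class
(concentrated direct beam + diffuse) and a shaded class (diffuse only)
weighted by the sunlit fraction — the standard two-class turbid-medium
treatment rather than a full within-voxel PPFD distribution. Canopy A_h
and E_h are leaf-area-weighted means per unit leaf area. Days integrate
as A_c = Σ A_h·1800·10⁻³ (mmol m⁻² d⁻¹), E_c likewise (mol m⁻² d⁻¹),
WUE_c = A_c/E_c, and are classed sunny (PPFD_d > 45 mol m⁻² d⁻¹), cloudy
(< 15) or intermediate (retained in output, excluded from sunny/cloudy
contrasts).

The switching design crosses leaf distribution with leaf function over
the four interstock × cultivar treatments: S0 (a–d) identity pairs, S1
(e–h) cultivar-swapped functions at fixed interstock, S2 (i–l)
interstock-swapped functions at fixed cultivar. Variance partitioning
uses sequential (type I) sums of squares on the two-way model with
interaction — order-invariant on the balanced synthetic designs used
here; unbalanced real data would require an explicit SS-type choice.
Post-hoc comparison is by pairwise Welch t-tests. Model validation uses
RMSE and RRMSE (= RMSE/mean(observed)·100) with accuracy classes
excellent < 10 % ≤ good < 20 % ≤ fair < 30 % ≤ poor.

## Synthetic data

The generator emulates the study conditions from known ground truth: an
ellipsoidal spindle crown with downward-biased shoot axes (100–120° from
vertical, mimicking scaffolds tied below horizontal) and a realistic
fruiting-tree shoot census (default 140 long / 260 short / 60 bourse
shoots, giving LAI near 1–1.5 at the default allometry); half-hourly
weather whose diurnal PPFD follows the sine of solar elevation scaled so
each day integrates exactly to its class target (sunny 48–56, cloudy
6–12, intermediate 22–38 mol m⁻² d⁻¹ — cloudy days add multiplicative
variability before rescaling, so generated labels always agree with the
classifier); A–Ci observations from the forward model at the 12-step
chamber protocol (C_i from the diffusion identity at a fixed chamber
conductance of 0.3 mol m⁻² s⁻¹) plus Gaussian noise; and single-factor
stomatal response curves (other drivers at the holding values PPFD 1500,
T 30 °C, VPD 1.2 kPa, whose constant factors divide out of the
normalized response). One global seed fans out into independent
per-operation substreams; fixed seed means byte-identical outputs.

What the synthetic conditions do not emulate: measurement error
structure beyond i.i.d. Gaussian noise, within-shoot leaf-size gradients,
shoot curvature, temporal nitrogen dynamics, row-neighbor shading
(isolated-tree simulation), and soil water limitation. Parameter-recovery
results therefore demonstrate the correctness of the inverse machinery
under the stated noise model, not field-data performance.

## Numerical choices and limitations

- Root finding: Brent's method throughout; C_i tolerance 10⁻⁴
  µmol mol⁻¹, energy-balance residual < 0.01 W m⁻².
- Ray sampling: default entry-plane spacing is half the smallest voxel
  edge; whole-canopy interception changes < 3 % when the voxel edge is
  halved from the default.
- Test problem sizes (grids of a few hundred voxels, trees of a few
  hundred to a few thousand leaves, seasons of 2–4 days) were chosen so
  the full suite exercises every code path at interactive speed; all
  engines accept full-size problems unchanged.
- No mesophyll conductance, no TPU limitation, no Ball–Berry-type
  g_s–A feedback (the Jarvis formulation is deliberate), no multiple
  scattering, no within-canopy microclimate gradients, no fruit sink
  feedback.
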