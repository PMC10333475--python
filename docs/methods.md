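# Methods

## Arch phantoms

All phantoms are planar centerline + radius models in the oblique-sagittal
measurement plane (x horizontal, y vertical, z = 0; world units mm), the
plane in which pediatric arch morphometry is read off MIP reconstructions.
The reference chord for "horizontal" and "vertical" is the **T-line**: the
segment from the end of the ascending aorta (landmark E) to the midpoint of
the descending aorta (landmark M). Width T = |EM|; height A = perpendicular
distance from the centerline's apex — on the arch side of the T-line — to
that chord. Defining both relative to the T-line rather than to the image
frame makes every output invariant to rigid motions; for phantoms generated
upright the two frames coincide.

Shape families are built from line segments and circular arcs so that A and
T hold exactly by construction:

* **gothic** — two near-straight limbs meeting at a corner above the arch,
  filleted by a small apex arc (radius 0.2·min(T, A)); the corner height is
  the one root of "fillet top = A" (Brent, 1e-12 mm).
* **crenel** — vertical limbs, a flat top at height A, quarter-circle
  corners (radius ≤ min(0.25 T, 0.45 (A − h)) with h half the descending
  length).
* **romanesque** — a single circular arc through both shoulders with apex
  height A (closed-form circle; a semicircular template yields A/T = 0.5).

The ascending aorta continues vertically below E (default length 0.7 T);
the descending aorta runs vertically below the arch with M at its midpoint
(default length clip(0.8 A, 17, 40) mm — the domain is truncated, standing
in for "to the diaphragm", and capped so M never rises above the arch).
Geometrically impossible requests (apex below the descending midpoint,
crowded stations, unsatisfiable angles) raise an error naming the
conflicting parameters.

**Chord angles.** The AAO line joins the start of the ascending aorta to
the anterior-border landmark of the brachiocephalic trunk (B); the DAO line
joins the descending end to the posterior-border landmark of the left
subclavian artery (S); the TAO chord joins B to S. AAO-DAO is reported as
the acute intersection angle of the AAO and DAO lines (printed group values
of 27–35° are acute); TAO-DAO as the angle at S between the rays S→B and
S→(descending end), the only ray convention that produces the ~110° values
tables report for near-perpendicular chords. The generator places B and S
on the arch by nested Brent solves so both requested angles hold to
~1e-12°; the left common carotid landmark sits midway between them. Because
the landmarks double as angle controls, the cohort sampler can only realize
angle draws that are geometrically consistent with the sampled A, T
(see *Cohort sampling*).

**Level stations and radii.** AOA sits mid-ascending ("at the level of the
main pulmonary artery"), D1/D2 midway between the branch landmarks, D3
mid-isthmus, D4 at M, D5 3 mm inside the descending end (so the diameter
search window never runs off the domain). The radius profile is constant on
a ±3 mm plateau around each station with smooth cosine blends between
plateaus; the plateau exceeds the ±2.5 mm measurement window, so the
windowed maximum recovers the generated diameter exactly. A stenosis
multiplies the radius by 1 − severity·w(s), w a cosine taper (default full
length 8 mm) peaking at exactly 1, so the throat radius is
(1 − severity)·(local radius) by construction. Cohort phantoms encode the
coarctation through the sampled level diameters themselves (D3/AOA in a CoA
cohort is already the narrowed value) and carry no extra stenosis element;
the explicit element belongs to the hemodynamic phantom, where the
unstenosed caliber and the constriction must be separated.

**Voxelization.** The binary mask is the union of tubes (main vessel +
three branch stubs); each voxel center is tested against the nearest
centerline sample *of each structure* (testing only the globally nearest
sample would let a thin branch passing through the main lumen carve holes).
A Nyquist-style guard requires spacing ≤ min radius / 2. Landmark world
coordinates pass through unchanged.

## Morphometry

The analytic path reads diameters off the radius profile and the geometry
off the exact landmarks, and round-trips every generated quantity to 1e-6
relative (tested on 100 random feasible phantoms).

The image path mirrors what one would do with a segmented CTA:
skeletonization (scikit-image), a 26-connectivity graph over skeleton
voxels, and the weighted-longest path (double-sweep Dijkstra) as the vessel
axis — which implicitly prunes branch stubs. Two artifacts of 3-D thinning
are corrected: the path is extended along its end tangents until the
distance map begins its end-cap falloff (thinning erodes blunt tube ends by
several radii), and each point is re-centered to the centroid of near-
maximal distance-map positions in its perpendicular plane (thinning drifts
off-axis near branch junctions). Radii are *cross-sectional* maximal
inscribed radii estimated from boundary voxels in a thin slab perpendicular
to the local tangent (plus half a voxel, since boundary-voxel centers sit
inside the surface); the 3-D distance transform itself underestimates
diameters near vessel ends. Skeleton loops are tolerated up to ~20 mm of
cycle length (junction artifacts); larger loops abort with the loop
location. At 0.4 mm spacing the extracted centerline lies within ~0.1–0.2
mm (mean) of the true axis, A/T is recovered within 2 % and level diameters
within about one voxel.

Measurement conventions: level diameters are the maximum inscribed diameter
within ±2.5 mm of arc length around the station (the search extent is a
physical choice — when measuring geometry rescaled by k, scale the window
by k as well); classification is gothic iff A/T > 0.8, crenel iff
A/T < 0.6, romanesque on the closed interval between (boundary values fall
to romanesque); hypoplasia flags use strict inequalities D1/AOA < 0.60,
D2/AOA < 0.50, D3/AOA < 0.40; the CoA flag fires when the smallest level
diameter is ≤ 50 % of the reference (default D4). Angles are reported to
0.01°.

## Cohort sampling

Group summaries are (mean, SEM, n) triplets; the shipped table encodes the
published three-group cohort (gothic/crenel/romanesque n = 27/25/43). The
± column is interpreted as the **standard error of the mean**, not the SD:
under sd = SEM·√n the printed F statistics of the reproducible rows come
out to within 0.2 % (see *Statistics*), under the SD reading none do.

Each case draws every variable independently from Normal(mean, SEM·√n),
truncated to positivity and to generous feasibility clamps (A/T ∈
[0.33, 1.05], AAO-DAO ∈ [8°, 60°], TAO-DAO ∈ [95°, 160°], Di/AOA ≥ 0.12)
by redraw. Quantities the table does not constrain get pediatric-scale
defaults: T ~ N(36, 4) mm, AOA ~ N(12, 1.5) mm, branch calibers scaled by
AOA/12. By default every returned case is verified against the builder,
redrawing geometrically infeasible combinations. Two biases follow and are
accepted: (i) variables whose SD exceeds their mean (age in this cohort)
are strongly right-shifted by the positivity truncation — the underlying
clinical distribution is skewed and a truncated normal is only a stand-in;
(ii) joint angle/shape feasibility rejection shifts cohort angle means by a
few degrees relative to the printed ones. The summary-statistics analyses
(the acceptance path) operate on the printed triplets directly and are
unaffected. Sampling is seed-deterministic, and with feasibility checking
disabled the grand mean converges to the specified mean (Monte-Carlo check
at ~10⁴ draws, tolerance 0.005 on A/T).

## Statistics

`anova_from_summary` implements fixed-effects one-way ANOVA from summary
triplets (SSB between group means weighted by n, SSW from sem·√n), which is
algebraically identical to raw-data ANOVA when the triplets come from the
raw data (oracle-tested against scipy on random datasets) and collapses to
the pooled two-sample t² for two groups. Of the printed test-statistic
column, six rows reproduce under this model within 1 % (D1/AOA 1.168,
D2/AOA 0.440, D4/AOA 3.155, D5/AOA 4.725, AAO-DAO 7.321, weight 2.754), as
does the gender χ² (2.99 from the printed counts). Five rows do **not**
reproduce (printed vs recomputed): D3/AOA 3.692 / 5.955, A/T 47.107 /
47.80, TAO-DAO 1.724 / 1.694, age 2.096 / 2.052, PSPG 0.742 / 0.640 — most
plausibly typos or a different post-hoc in the source; they are reported
with a `reproduces: false` flag and excluded from the reproduction checks.
The PDA row's printed count (35 = "83.3 %" of 43) is internally
inconsistent and its χ² (0.670 printed vs 1.364 from counts) likewise does
not reproduce.

Raw-sample group tests follow the clinical recipe: KS normality per group
against a Normal with estimated parameters (the Lilliefors caveat — this is
mildly conservative — applies), Levene with center = mean, then pooled
Student t / classic ANOVA when Levene does not reject at α = 0.05 and
Welch otherwise. χ² is Pearson's without continuity correction. No
multiple-testing correction is applied across table rows (none is applied
in the workflow this mirrors). Type-I error of the t and Levene paths is
Monte-Carlo-calibrated in the tests (2000 null replicates, 5 % ± 1.5 %).

## Hemodynamics

The flow model is a one-dimensional rigid-wall incompressible Newtonian
network: five main segments (ascending, proximal arch, distal arch, isthmus
with the stenosis element, descending) and three branch outlets, with
geometry taken from the gothic phantom's junction arc lengths and radius
profile so junction diameters are continuous by construction. Defaults:
ρ = 1050 kg/m³, μ = 0.0035 Pa·s (the viscosity is dynamic — its units are
Pa·s), cardiac period 0.8 s, Δt = 5 ms (160 steps/cycle), inlet peak
velocity 1.2 m/s as a half-sine over a 0.35 systolic fraction with zero
diastolic inflow, constant outlet pressures 120 mmHg (arm; the three
branches) and 65 mmHg (leg; descending). The default phantom's level
diameters are *normal* pediatric calibers (AOA 12, D1 10.2, D2 9.0, D3 7.0,
D4 8.5, D5 7.8 mm): the narrowing enters solely through the stenosis
element, whose throat area ratio A_s/A₀ is the free calibration parameter —
after calibration the effective throat (~3.1 mm) lands close to the
measured isthmus caliber of a gothic CoA group (D3/AOA ≈ 0.26 vs 0.29).

Each segment contributes viscous (Poiseuille integrated in closed form over
the linear taper), convective and inertial (ρ·dQ/dt·∫dx/A, backward-
difference dQ/dt) pressure changes; the stenosis adds the Young–Tsai
element with K_t = 1.52, K_u = 1.2 and K_v = 32 (L_s/D₀)(A₀/A_s)². One
deliberate closure choice: convective head is kept (ideal Bernoulli) where
flow accelerates but treated as fully dissipated where it decelerates
(no diffuser recovery, Borda–Carnot-style), in both flow directions. The
ideal even-in-Q recovery term otherwise makes the outlet-path system
genuinely unsolvable during diastolic flow reversal and at near-open
throats; with the dissipative closure each path loss is monotone in its
flow and the per-step nonlinear system (branch flows + inlet pressure;
mass conservation is built into the parameterization, so ΣQ_out = Q_in
holds to round-off) has a unique solution. It is found by damped Newton
(finite-difference Jacobian, backtracking line search, 200-iteration cap)
with a MINPACK dogleg polish as fallback after a detected stall. Cycles are
marched until the inlet-pressure curve changes by < 1e-4 (relative, max
norm) between cycles — three cycles at the defaults — and the last cycle is
reported. Halving Δt moves the peak transstenotic drop by < 0.1 %.

Outputs: peak-systolic axial pressure/velocity profile (stenosis losses
distributed over the throat cells, so the sharpest dP/dx localizes in the
throat), the transstenotic drop read between the pre-stenotic junction node
and the mid-descending station, throat jet velocity, per-segment Reynolds
numbers (laminar friction is retained even when Re > 2300, matching the
laminar modeling assumption; violations are reported as diagnostics, and
the calibrated case does exceed 2300 in several segments — consistent with
the turbulence seen distal to the stenosis in the imaging-based
simulation), and the simplified (4v², mmHg) and full (½ρΔv²/133.322)
Bernoulli gradients, whose ratio is the constant 4/3.938 ≈ 1.016.

**Calibration.** `calibrate_stenosis` bisects the constriction A₀/A_s in
[1.05, 50] until the simplified-Bernoulli gradient of the solver's peak jet
matches the Doppler PSPG target within 0.1 mmHg. Under the default outlet
pressures the arm/leg difference pins the available transstenotic drop near
55 mmHg, which makes the Bernoulli gradient a *decreasing* function of the
constriction (opening the throat raises flow and jet speed); targets from
~37 mmHg (saturated, tight throat) up to several hundred mmHg (open throat)
are reachable and the 57.2 mmHg target calibrates to A_s/A₀ ≈ 0.136.
Re-calibration of an already-calibrated network is a fixed point. At the
calibrated point the solver's own transstenotic peak-systolic drop is
~64 mmHg, within 15 % of the ~58 mmHg reference value, the jet is 3.78 m/s
(> 2 m/s), and pre-stenotic velocities stay within the 1.2–1.7 m/s laminar
band. The absolute outlet levels matter little for these loss-dominated
quantities (shifting both outlets together shifts pressures, not drops);
the arm–leg *difference* is the sensitive input, as expected for a model
whose gradient is BC-forced.

## What the synthetic data does and does not emulate

The phantoms reproduce the measured *quantities* of an arch-morphometry
study — exact heights, widths, angles, diameters and their group
statistics — not patient anatomy. Centerlines are planar (no out-of-plane
tortuosity), branches are short stubs, radii are piecewise-plateau, caps
are hemispherical, and masks are noise-free with perfect segmentation.
Passing tests therefore demonstrate the correctness of the measurement and
modeling machinery, not robustness to real CTA noise, motion, or anatomical
variants. The 1-D flow model preserves the stated physical parameters and
pressure-drop physics but cannot reproduce 3-D flow fields, secondary flow,
jet eccentricity or wall shear stress; constant-pressure outlets force an
unphysiological diastolic recirculation (real diastolic runoff is
compliance-driven), which is confined to the zero-inflow phase and does not
affect the peak-systolic metrics reported. No ductus arteriosus shunt or
collateral circulation is modeled.

## Problem sizes

Defaults keep every stage desk-scale: a 95-case cohort generates and
measures in a few seconds; a 0.4 mm voxelization of one arch is ~1–2
million voxels and the image path runs in ~2 s; one pulsatile solve is
160 steps × ≤10 cycles (~0.3 s) and a calibration ~25 solves. The full test
suite runs in about a minute on one CPU.
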