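# Methods

This note records the models, parameter choices and numerical decisions
behind `mfstretch`, in the spirit of a methods section: what is assumed, what
is computed, and what the synthetic data can and cannot say about real
experiments.

## Stress–strain analysis

One experiment consists of a calibrated cantilever (spring constant
k_p ± SD), an aggregate geometry (R0, L0, each a mean ± SD over five repeat
measurements), and a deflection trace x(t) sampled at the camera frame rate
(30 s⁻¹).  Engineering conventions are used throughout: stress is normalised
by the *initial* cross-section π R0² and strain by the *initial* length L0,
with ΔL = x_s − x and x_s = v·t when the motor position is not itself
tracked.  No incompressibility correction is applied to R during stretch;
this matches how cell-aggregate stretching data are conventionally reported
and makes moduli directly comparable across studies.

**Young's modulus.** E is the ordinary-least-squares slope of σ on ε over
the first w points of the curve.  The window policy scans w ∈ {10…30} and
keeps the w with the highest R², resolving ties towards the larger window
(an exact line therefore uses all 30 points); a fixed-w policy (default 20)
is available for strict reproducibility.  An intercept is fitted and
discarded — the first frames can carry a small offset from the acceleration
ramp and from tracking the first template — and the reported uncertainty is
the standard error of the slope.  The ≤1-frame acceleration phase
(1 mm s⁻² to 20 µm s⁻¹ lasts 20 ms) is included in the fit window; its
effect is below the per-point noise.

**Ultimate tensile strength.** The maximum engineering stress over the
trace.  When the aggregate slipped in a pipette (an operator annotation),
σ_UTS is withheld but E is still reported, since slip events occur near peak
load, after the elastic window.

**Error propagation.** First-order propagation of the three calibrated
inputs only: σ_err/σ = sqrt((sd_kp/k_p)² + (2 sd_R0/R0)²) and
ε_err/ε = sd_L0/L0.  Deflection noise is deliberately excluded — error bars
describe systematic calibration/geometry uncertainty, not per-frame jitter.
The closed forms are validated in the tests against 10⁴-draw Monte-Carlo
propagation with *log-normal* parameter perturbations: normal perturbations
at 10% CV place mass at R0 ≤ 0, where moments of 1/R0² do not exist, so the
log-normal family is the well-posed positive-parameter choice.

**Quality control.** Four exclusion rules: (i) *jump* — any frame-to-frame
stress step exceeding 10× the median step over the loading portion of the
curve (up to the stress maximum).  Jumps are suction-pressure artifacts and
corrupt loading; the post-peak rupture cascade, by contrast, is genuine
failure physics and is not screened.  (ii) *no_stretch* — rupture before
ε = 0.02.  (iii) *vertical_drift* — the tracked tip drifts more than 3 px
off the stretch axis.  (iv) *rotation* and *slip* are operator annotations.
Invalid experiments still appear in output tables with `valid = False`.

## The spring-chain model

Each cell (radius r_c) plus its share of cell–cell adhesion bonds is lumped
into one Hookean spring k_c.  Axial force chains contain n_x =
round(L0/2r_c) springs in series; the cross-section carries n_A =
round(R0²/r_c²) chains in parallel (both floored at 1, round-half-up, so a
single cell is representable).  Series/parallel composition gives
E ∼ k_c/r_c with a prefactor of order one.

Two deliberate choices:

- **Prefactor 1 for inference.**  The inverse map k_c = E·r_c uses prefactor
  exactly 1, matching the arithmetic by which the single-cell stiffness is
  quoted from the measured cohort (248 Pa × 3.3 µm = 8.2×10⁻⁴ ≈ 8×10⁻⁴
  N m⁻¹).  The lattice-derived constant c ≈ 0.55 is reported separately and
  never silently substituted.
- **Lattice realisation.**  The oracle network is a simple-cubic lattice
  with spacing 2r_c, axial bonds only (stiffness k_c, rest length 2r_c);
  nodes are kept when they fall inside the nominal cylinder, and the first
  and last planes are clamped.  Lateral bonds are a config option, off by
  default — the axial response is assumed to be dominated by bonds along the
  stretch axis.  Each node carries a single scalar axial degree of freedom;
  the equilibrium is a sparse graph-Laplacian solve, with connected-component
  analysis so ruptured, floating fragments are force-free rather than making
  the system singular.  A disconnected network reports stiffness 0 with a
  flag instead of raising, so rupture sweeps terminate cleanly.
- **Specimen modulus.**  The modulus of a lattice specimen uses its realized
  clamp-to-clamp length n·2r_c (the distance the solver actually spans) and
  the nominal cross-section πR0².  On the validation grid (R0/r_c ∈ {3,5,8},
  L0/r_c ∈ {6,10,20}) the resulting constant c has CV ≈ 11%, the residual
  variation being lattice discreteness (integer chain counts in a circle —
  Gauss-circle fluctuations), not a size dependence.

## The simulator

`simulate_stretch` couples the cantilever and the network quasi-statically:
per frame the motor position follows the trapezoidal profile, and the
deflection x solves k_p·x = F_agg(x_s − x) by bisection on x ∈ [0, x_s].
Inertia and viscosity are dropped: at 20 µm s⁻¹ over ∼100 µm the loading
time is far slower than cellular elastic response, and no relaxation law is
resolvable from stretch-at-one-speed data.  With bond states frozen the
network is linear, so one unit solve per state configuration gives both the
tangent stiffness and every bond strain by scaling; state transitions
(elastic → yielded → broken) are applied as a within-frame fixed point,
which terminates because damage is monotone.

**Plasticity.**  Bonds carry two strain thresholds: at the yield strain the
bond's stiffness drops to 0.1×k_c (secant damage, rest length unchanged); at
the rupture strain the bond is removed.  Per-bond thresholds get one
multiplicative log-normal jitter (CV 0.2, same factor for both thresholds so
yield ≤ rupture is preserved), which staggers chain failures and produces the
ductile shape — linear regime, decreasing slope, stress maximum, progressive
post-peak decay — rather than a single brittle drop.  Defaults are
yield_strain = 0.5 and rupture_strain = 3.0 *per bond*: once a bond yields,
its chain's extension localises in it (≈5× concentration in a ten-cell
chain), so rupture/yield must exceed ≈5 for any stable plastic regime, and
these values make whole aggregates fail near engineering strain 1, as
ductile cell aggregates do.

**Double stretch.**  Relaxation during the ∼9 s wait between stretches is
not modelled mechanistically; the pre-stretch history is subsumed into one
softening factor (default 0.7) applied to every cell spring before the
second stretch.  The analysis recovers this factor as E2/E1.

**Rendering.**  Frames show dark silhouettes on a bright background: the
straight pipette entering from the left, the L-shaped sensor (vertical
cantilever plus horizontal arm, whose elbow is the tracked feature), and the
aggregate as a cylinder whose drawn area is conserved as it elongates, with
a speckle texture advected in material coordinates.  Objects are placed with
sub-pixel anti-aliased coverage, then blurred (σ = 1 px) and given additive
Gaussian pixel noise (SD 2 grey levels).  Default optics: 0.5 µm/pixel,
256×768 frames.  This is deliberately *not* phase-contrast realism: it is
sufficient to exercise template tracking and silhouette segmentation, and no
more.

## Tracking and geometry

The sensor tip is tracked by normalized cross-correlation of a frame-0
template (skimage `match_template`) over a search window, with parabolic
sub-pixel refinement of the correlation peak in both axes; deflection is the
horizontal displacement relative to frame 0 (leftward positive — the pull
direction), converted to metres at the module boundary.  Quality is the peak
correlation; >5% of frames under 0.5 raises a tracking failure naming the
first bad frame.  Vertical tip motion is reported as a drift metric, never
subtracted.  Measured accuracy on rendered stacks: <0.03 px noise-free,
<0.05 px at SD-2 pixel noise.

Geometry comes from the first frame: after Otsu binarisation, the aggregate
is the only silhouette extending below the pipette axis, so the dark-column
span in the band below the straight pipette gives the gap between the two
pipette openings (L0), and the full silhouette height at five axial stations
gives R0.  The five-repeat protocol is emulated honestly: R0 repeats are
five different stations across the cluster, L0 repeats are five
re-detections with jittered binarisation thresholds, and the reported SDs
feed the error propagation.  The aspirated total volume V_tot is accepted as
optional metadata only; no in-pipette segmentation is attempted.

## Calibration

Droplet weights: the resting drop is a spheroid, V = (4/3)π a b² with b the
vertical semi-axis (sphere limit unaffected), W = ρgV, and k_p = W/Δx per
droplet; repeats give mean and sample SD.  Buoyancy in air and evaporation
are not corrected.  The synthetic generator draws drop sizes in 0.3–0.7 mm,
computes exact deflections from a known k_p, and corrupts only the reported
axes — so noise-free observations of any drop size give identical k_p (a
units/shape audit) and 1% axis noise propagates to ≈3% per-droplet scatter.

## Group-level statistics

The generator emulates the study's structure: per-mouse log-normal baseline
moduli, condition ratios applied multiplicatively (reference 1.0, +W-7 2.8,
anti-CD3 0.30), and within-mouse multiplicative noise; every mouse is
measured under every condition, with 10 aggregates per mouse-condition
(within the 5–25 clusters measured per sample) and 15 mice per group by
default.  The pooled reference distribution is constrained to mean ≈ 248 Pa
with SD ≈ 234 Pa; a log-normal is the simplest positive law with SD ≈ mean.
The variance split — between-mouse log-SD 0.45, within-mouse log-SD derived
from the pooled total (≈0.66) — was fixed once so that the same-mouse ratio
spread across mice (≈±0.7 on a ratio of 2.8) matches the reported scale.
Null covariates (volume, aspirated fraction, hours post-activation) are
attached with no effect on E.

Because aggregates from one mouse are correlated, group comparisons first
aggregate to per-mouse means — the mouse is the independent unit — and then
apply Welch's unequal-variance t-test (manual Welch–Satterthwaite df,
verified against scipy).  Running Welch on pooled aggregates would be badly
anti-conservative under the mouse random effect (measured type-I ≈ 0.36 at
α = 0.05); on per-mouse means with independent cohorts it is calibrated
(measured ≈ 0.05).  Note that on *same-mouse* data the unpaired test is
conservative — the paired structure is instead exploited by the same-mouse
ratio estimator (per-mouse group means, ratio per mouse, mean ± SD across
mice).  Stars follow p < 0.05/0.01/0.001/0.0001; no multiple-testing
correction is applied, matching pairwise reporting.  Box summaries use
type-7 (linear-interpolation) quartiles and 1.5×IQR whiskers placed on the
most extreme points inside the fences; the quartile convention is a
documented choice since plotting software varies.

Covariate null checks fit a least-squares slope of E on the covariate and
report whether the 95% CI contains zero ("flat").

## Problem sizes and determinism

All randomness flows from single integer seeds through `numpy` Generators;
fixed seeds give byte-identical outputs.  The validation suite uses 20
rendered end-to-end experiments for recovery, 50 seeds × 7 volumes for the
volume-independence null, 100 seeds for group-statistics power, 2000
replicate pairs for the Welch type-I calibration, and 10⁴ Monte-Carlo draws
for error propagation — sizes chosen so each check's Monte-Carlo error is
small against the property being asserted.

## What passing tests do and do not show

The synthetic layer shares the measured experiments' kinematics, noise
scales and statistical structure, but not their biology: no active cell
motility or "shivering", no viscoelastic relaxation (a single softening
factor stands in for it), no suction-pressure fluctuations (jumps are tested
with injected artifacts), binary-silhouette optics rather than
phase-contrast, and a regular lattice rather than random packing.  Passing
tests therefore demonstrate that the *pipeline* is correct and unbiased on
data with known ground truth and realistic noise — not that the mechanistic
model is the true constitutive law of T-cell aggregates.  Real-cohort values
(E = 248 ± 234 Pa, σ_UTS = 390 ± 334 Pa, the condition ratios) enter only
as generator parameters and plausibility ranges.

## Known limitations

- Single stretching speed; no rate-dependent (viscoelastic) fitting.
- The lattice oracle's prefactor c ≈ 0.55 is specific to simple-cubic
  axial-bond packing; random close packing would shift it (the scaling in
  k_c/r_c would not change).
- The UTS/E ratio of simulated aggregates (≈0.4–0.5) is below the measured
  cohort's (≈1.6): secant damage cannot sustain stress far beyond yield.
  Recovery tests are against simulator ground truth, so this limits realism,
  not validity.
- Geometry segmentation assumes the rendered scene convention (stretch axis
  horizontal, pipettes near the optical axis, aggregate the only object
  below it); measured videos with different layouts would need a new
  segmentation front-end, not a new pipeline.
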