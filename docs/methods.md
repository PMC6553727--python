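# Methods

## Corneal model

The cornea is two coaxial, rotationally symmetric conicoid surfaces in a
right-handed frame with +z from air into the eye and the origin at the
anterior apex; lengths are mm, powers diopters (lengths converted to
metres at the point of power computation). A conicoid with apical radius
`R` and asphericity `Q` has sag `z(r) = r²/(R(1 + √(1 − (1+Q)r²/R²)))`.
The posterior apex sits one central thickness behind the anterior apex;
surfaces are validated not to intersect within an 8 mm aperture. Toricity,
tilt and decentered posterior surfaces are out of scope: the analysis
concerns scalar mean powers, and astigmatism enters only through the
spherical-equivalent refraction.

Default asphericities are anterior Q = −0.25 and posterior Q = −0.20,
representative physiologic prolateness; neither is constrained by the
published cohort summary, so both are configuration, not inference.
Refractive indices: air 1.0, cornea 1.376, aqueous 1.336, and the
fictitious keratometric index 1.3375 used only for keratometry-convention
conversions.

## Ray tracing and per-ray power

Rays enter parallel to the optical axis. The anterior intersection of an
axis-parallel ray is the sag itself; the posterior intersection solves the
ray/conicoid quadratic in closed form (the paraboloid, Q = −1, degenerates
to a linear equation which is solved exactly). Refraction uses the vector
form of Snell's law; the Snell invariant `n·sin θ` is conserved to 1e−12
and total internal reflection is an explicit error.

Per-ray power is the "Snell power" `P(h) = n_aq · sin U′ / h` with `U′`
the exit ray's angle to the axis and `h` the entry height from the
aggregation center. Its paraxial limit equals the Gaussian thick-lens
equivalent power `P1 + P2 − (d/n_c)P1P2` (verified to < 1e−4 D at
h = 5 μm over randomized physiologic corneas), which makes the paraxial
oracle a structural self-check rather than an assumption. An alternative
definition, `n_aq` divided by the axial crossing distance measured from
the posterior apex plane, is available behind `definition="crossing"` for
sensitivity analysis; paraxially it converges to the back-vertex power
instead, which is the main reason it is not the default.

### Centration

Ring/zone aggregation is centered on either the corneal apex or the pupil
center (apex shifted by the pupil-offset vector). Ray heights — both the
sampling grid and the `h` in the power definition — are measured from the
chosen center while rays stay parallel to the common axis, mimicking
instrument-axis acquisition with off-axis aggregation. A consequence worth
knowing: with a decentered pupil the per-ray power behaves like
`P·|offset|/h` as `h → 0` because rays near a decentered center still
carry a nonzero exit angle, so pupil-centered values at very small
diameters (≈ 1 mm) are inflated relative to apex-centered ones. The
integrand is still integrable (zone weights scale with h), quantities at
the clinically reported diameters (2–8 mm) are essentially unaffected, and
with zero offset the two centrations coincide exactly — that exact
coincidence is a tested invariant.

### Ring and zone quadrature

The default grid samples radial nodes every 0.05 mm with 256 meridians
(64 in the cohort pipeline; ring values are stable to < 1e−6 D beyond 32
meridians on symmetric corneas). A *ring* value is the unweighted meridian
mean at exactly d/2, with linear radial interpolation between nodes. A
*zone* value is the area-weighted mean over the filled disc: each sample
at node r_j carries its annulus-sector area, the innermost annulus extends
to r = 0 (so the d → 0 limit is the central power) and the outermost is
clipped at the zone edge. Ring and zone statistics require ≥ 90% of their
samples/area to be traceable and fail loudly otherwise; silent
extrapolation would bias exactly the peripheral diameters the analysis
cares about. The tomographer's proprietary focal-length conversion and
weighting cannot be replicated; these definitions are declared stand-ins
validated through their paraxial, symmetry and monotonicity properties.

## Keratometry formulas

`Km = 0.3375/r1`, `TNP = 0.376/r1 − 0.040/r2`,
`EKR = 0.376/r1 − 0.03165/r2` (all radii metres). The printed EKR formula
has no diameter dependence, so the "4.0 mm" and "4.5 mm" names evaluate
identically on synthetic data and differ only for imported device exports.
In the synthetic pipeline Km and EKR are evaluated from apical radii —
rotational symmetry makes meridian selection moot — while imported cohorts
supply instrument-exported values directly.

CHM subtracts the corneal-plane refractive change from the preoperative
Km, with the spectacle-to-cornea conversion `F_c = F/(1 − d·F)` at a
default vertex distance of 12 mm (a conventional refraction-lane value;
the source study does not print one). Haigis (`1.119·Km − 5.78`) and
Shammas (`1.14·Km − 6.8`) act on the set's own postoperative Km. The
modified TCRP adds a fixed 0.70 D conversion to the 4 mm zone TCRP.

## Synthetic cohort

Preop Km, preop SE and the surgical target SE are truncated-normal draws
(rejection-free, via the truncated-normal distribution itself) at the
published cohort moments and ranges; preop Km and SE are drawn
independently because no per-eye covariance is published. Geometry:
`r1 = 337.5/Km` mm, `r2 = 0.822·r1`, central thickness N(0.540, 0.030) mm
clipped to physiologic bounds, pupil offset N(0, 0.1 mm) per axis, optical
zone drawn from {6.0, 6.5} mm.

The lenticule reshape is invented structure (the study describes the
surgery, not a shape equation) and all its constants are configuration:
anterior keratometric power drops by the corneal-plane change to the
*target* SE; thickness drops by the Munnerlyn-approximation lenticule
`ΔSE·OZ²/3` μm plus a 15 μm base; anterior Q shifts oblate by +0.08 per
diopter so that ray-traced power rises toward the periphery as measured
post-myopic maps do. The posterior surface and pupil offset are untouched.
Nothing downstream depends on these exact constants — only directions and
moment recoverability are asserted.

Measurement noise: recorded manifest SE = target + N(0, 0.15 D) (the
target SD is shrunk to √(0.40² − 0.15²) so the achieved SE matches the
published 0.40 D spread), and measured radii carry N(0, 0.01 mm) noise,
with the posterior radius sharing one draw across visits so the
"posterior unchanged by surgery" invariant holds in the measured models
too. With both noise terms at zero the CHM of each eye equals the
postoperative anterior keratometry *by construction* (the reshape is
defined through the keratometric convention) — a useful consistency check,
and an honest statement of what the generator cannot show: the real
study's Km-vs-CHM bias (+0.78 D) arises from device physics the generator
does not model, so synthetic biases are not comparable per-eye to the
published ones. Directional patterns (TNP < EKR < Km, zone power rising
toward 8 mm, ring > zone at 8 mm) are what the synthetic pipeline can and
does reproduce.

## Statistics

Bland–Altman: bias = mean(x − y), SD with n−1 denominator, LOA =
bias ± 1.96·SD (the identity is asserted on every report row). Pearson r
with the two-sided t-transform p. The omnibus comparison is a one-way
repeated-measures ANOVA (statsmodels AnovaRM) across CHM plus all method
columns; pairwise contrasts are paired t tests of each method against CHM,
Bonferroni-multiplied by the family size m = 20 (18 standard methods + 2
modified TCRP rows) and capped at 1; m is recorded in the report metadata.
Degenerate cases are explicit: all-identical columns report F = 0, p = 1;
a zero-variance nonzero difference reports p at a documented floor of
1e−15; correlations after exact equality are flagged missing rather than
forced to 1. Shapiro–Wilk normality annotates the report only — no
decisions hang on it. Sphericity corrections, regression-based LOA and
bootstrap CIs are deliberately out of scope.

## Problem sizes and determinism

Default analyses run 40 eyes (the study size) with 64-meridian maps;
moment-recovery studies use 5000 eyes with map construction skipped, since
only geometric/refraction moments and record invariants are examined.
Every random quantity flows from one named `numpy` Generator seeded from
the run configuration, and identical configurations produce byte-identical
CSV outputs.

## Known limitations

- Per-eye agreement with the published cohort (correlations ≈ 0.97, LOA
  widths) is not reproducible without the original per-eye data and the
  device's internal conversions; the package reproduces formula
  arithmetic, published-mean bias arithmetic, physics invariants and
  directional patterns.
- The pupil-centered small-diameter inflation described under
  *Centration* is a property of the declared per-ray power convention,
  not of the underlying optics.
- The reshape model ignores biomechanical remodeling, epithelial healing
  and astigmatic or decentered lenticules.
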