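# Methods

This note documents the models, conventions and numerical choices behind
`morphodim`, and what the synthetic generator does and does not emulate.

## Shape model and superimposition

Shapes are K landmarks in D ∈ {2, 3} dimensions. Superimposition is
*partial* generalized Procrustes analysis: each configuration is centred,
scaled to unit centroid size (CS = √Σ‖xᵢ − x̄‖², the standard geometric-
morphometrics size measure), and rotated onto an iteratively re-estimated
consensus by orthogonal least squares (Kabsch/SVD, reflections excluded);
no post-hoc cos ρ rescaling is applied. Iteration stops when the squared
displacement of the unit-size consensus falls below `tol` (default 1e-10,
`max_iter` 100). The reported consensus is the plain coordinate-wise mean
of the aligned configurations. Convergence is fast (2–3 iterations) at
realistic shape dispersion; maximally dispersed random shapes converge
linearly at a rate set by their dispersion and can need hundreds of
iterations — a property of the alternating update itself, not of the
implementation.

Tangent-space PCA is a covariance PCA of the vectorized aligned
coordinates about their mean. Orthogonal projection to the tangent space
is implicit in operating on Procrustes residuals; no exact Kendall-space
projection is applied — at the shape scales treated here (Procrustes
distances ≪ 1) the difference is far below the noise level.

Allometry is removed by multivariate regression of vectorized shapes on
log10 CS (raw CS available via `log_size=False`); residuals are exactly
orthogonal to the predictor and are re-attached to the consensus so
residual "shapes" remain plottable. Log10 is the default so shape and the
functional size corrections share one size scale.

## Missing landmarks

Thin-plate-spline interpolation uses the kernel U(r) = r² log r in 2D and
U(r) = −r in 3D, with a full affine polynomial part, so the interpolant
reproduces affine maps exactly. The reference for each incomplete
specimen is the GPA consensus of the complete specimens of its own
population (watershed × habitat); the specimen is superimposed on the
reference by a full similarity fit over its observed landmarks, the
reference's missing-landmark position is warped through the TPS fitted on
the observed landmarks, and the result is mapped back to the specimen
frame. A landmark missing from every specimen of a population is
unrecoverable and raises.

## Bilateral symmetry and side averaging

Object symmetry: each specimen and its mirrored-and-relabelled copy
(reflect across the last axis, swap paired landmarks; for lateral-view 2D
projections the mirror is pure relabelling) enter a joint GPA. The shape
ANOVA partitions variation into symmetric (individual), directional
asymmetry (side) and fluctuating asymmetry (individual × side). With one
digitization per side the fluctuating component is the residual, so its
R² is reported but it carries no test; the side effect is tested by RRPP
against the individual-only model. Digitization noise is inseparable from
fluctuating asymmetry in this design and inflates that component.

Side averaging assumes midsagittally oriented coordinates (the pipeline
orients first): the right side is reflected across Z = 0 and averaged with
the left. For 2D lateral projections the sides are averaged directly,
since Z-drop projection commutes with the mirror; equivalently, the 2D
one-sided dataset equals the projection of the 3D one-sided dataset.

## Midsagittal orientation and projection

The mirror plane is the least-squares plane through the midpoints of the
left–right landmark pairs (closed-form SVD solution — deterministic and
testable). The plane is mapped to Z = 0 with the left side at positive Z;
X is the first in-plane principal axis of the midpoints, signed so the
anterior tooth tip lies anterior. 2D data are the X,Y columns of oriented
configurations — an orthographic lateral view; no perspective model.

The common 2D–3D shape space follows the residual-superimposition idea:
within each dimensionality, shapes are aligned and centred about their
consensus by taking centroid-size-regression residuals (removing common
allometry at the same time); each dimensionality's consensus is then added
back so the joint GPA operates on shape-like objects, the 2D set is
embedded at Z = 0 (the only isometric embedding consistent with the
projection), and all 2N configurations are superimposed together. The
add-back is a package design choice where the procedure was genuinely
open; `add_consensus=False` superimposes raw residual matrices instead.

## RRPP linear models

Models are ordinary least squares on an (N, p) response with factors and
covariates. Term SS are Type II: each term is tested after every other
term that does not contain it (interactions are tested over the additive
model); Type II SS are order-invariant and sum to the model SS only in
orthogonal (balanced) designs. F uses the full-model residual mean
square. Significance comes from residual randomization: the residuals of
the term's reduced model are permuted (all terms share one permutation
schedule per fit), the statistic recomputed `n_perm` times, and
p = (1 + #{F* ≥ F}) / (n_perm + 1) — the observed arrangement counts, so
p ≥ 1/(n_perm+1), and ties count as exceedances (conservative). Z effect
sizes are standard-normal positions of log F within the permutation
distribution (log stabilizes the skew of F; configurable only in code).
Degrees of freedom are classical OLS df regardless of the permutation
inference. Saturated cases are defined explicitly: F = 0 when both term
and residual SS vanish, +∞ when only the residual does.

Defaults: 999 permutations for ANOVA-type tests and Mantel tests (plus
the observed arrangement = 1,000 total), 9,999 for pairwise vector
comparisons (= 10,000 total).

Phenotype vectors: per-group slope vectors of the response on a covariate
are extracted from the separate-slopes parameterization (equivalently,
within-group regressions). Angles are arccos of normalized dot products
(degrees, [0°, 180°]); magnitude comparisons use | |u| − |v| |, the
absolute difference of vector norms. Permutation p-values come from
permuting residuals of the common-slope (no-interaction) model. Groups
with fewer than 3 specimens spanning the covariate are flagged unstable.

Mantel r is the Pearson correlation of strictly-lower-triangle entries,
with joint row/column permutations of the second matrix (one-sided). The
2D–3D consensus-distance correlation log10-transforms each specimen's
distance to the consensus in each space; its parametric p is reported but
is not meaningful when both spaces derive from the same specimens.

## Kinematics

A four-bar linkage is specified by four joints with link roles — fixed
link between the two grounded joints, input link rotating about one of
them, output link about the other, coupler connecting the moving joints.
The landmark-to-link table is configuration data (a small overridable
mapping): Op4 uses landmarks {1,2,3,4} (fixed 2–3, input opercle 2–1,
coupler 1–4, output mandible 3–4); Max4 uses {3,6,7,8} (fixed 3–8, input
lower jaw 3–6, coupler maxilla 6–7, output nasal link rotating about 8 —
defined as the output so its rotation about a fixed axis is well posed);
the mandibular levers use jaw joint 3, opening in-lever 3–4, closing
in-lever 3–6 and shared out-lever 3–5 (lever ratio = in-lever/out-lever,
the standard convention).

KT is computed over a 10° input rotation (the conventional probe), in 20
increments. The planar solver closes the loop in closed form
(circle–circle intersection), choosing at each increment the intersection
continuous with the previous pose (minimum joint displacement), which
prevents branch-jump artifacts; locking mechanisms raise an error naming
the maximum feasible rotation. The 3D solver prescribes unit rotation
axes at the input and output grounded joints; with both links confined to
single-axis rotations the mechanism has one unknown per increment (the
output angle), found by bracketed root-finding on the coupler-length
closure condition with continuation from the previous increment and a
1e-9 mm residual tolerance. The output excursion is exactly the rotation
angle about the output axis. Axis tilts are given as (polar, azimuth)
degrees from Z, tilted within the YZ plane by default — the tilt
direction is a sweepable parameter, not a constant; the analysis defaults
tilt the Op4 input axis 30° and the Max4 output axis 20° from Z. The
input rotation sign is chosen in the jaw-opening sense (output joint
moving ventrally); if a noisy configuration cannot close in that sense
the pipeline falls back to the opposite sense and records a note.

KT and LR cannot be computed from shape residuals, so size correction is
downstream: each variable is regressed on the log10 CS of the complete
landmark set and the residuals are analysed (univariate ANCOVAs per
variable, a multivariate RRPP over all four, and a covariance PCA of the
four-variable matrix).

## Diet covariates

Gut contents are proportions per prey category. The Hellinger transform
(element-wise square root; unit row sum-of-squares) precedes a two-class
Fisher discriminant with pooled within-class covariance and a ridge
ε = 1e-8·tr(S_w)/p — compositions are collinear by construction. The LDA
is fitted on individual fish (too few fish per population for
per-population fits); scores are centred on the grand mean, signed so the
stream mean is positive, and population means serve as the diet-type
covariate. Classification (training) is by nearest class mean on the LD
axis. Gini–Simpson diversity 1 − Σpᵢ² is computed from population-summed
gut contents, not per-fish averages.

## Synthetic generator

`SimulationConfig` defaults define the emulated study: 6 watersheds × 2
habitats × 5 specimens; a stylized 8-landmark bilateral head template on
the mm scale (plausible proportions and feasible linkages, no anatomical
claim); habitat/diet effect vector of norm 0.2 mm with half its squared
norm in the width (Z) coordinates; watershed effect SD 0.08 mm and
watershed × habitat interaction SD 0.04 mm per coordinate; an allometric
pattern of 0.15 mm per unit log10 CS with lognormal sizes (log10 SD
0.08); directional asymmetry offset 0.04 mm; fluctuating asymmetry SD
0.02 mm and landmark noise SD 0.05 mm per coordinate (noise chosen as a
multiple of the µCT-scale digitization error; effect norm = 4 × noise SD
is the reference detection condition). Population diet scores are ±1 ±
0.2; diet compositions are Dirichlet draws with mildly shifted lake and
stream concentrations over 12 prey categories, chosen so individual diets
overlap heavily (≈ 65–70% assignable) while population means separate,
and population Gini–Simpson lands near 0.9. Specimens are placed in
random rigid digitization frames; no extra scale jitter is applied beyond
the size distribution, since landmarks are in mm and a frame-scale jitter
would corrupt the size covariate the allometric terms need. A single
master seed derives all sub-streams (per-specimen seed spawning), so any
subset regenerates stably; every drawn effect is returned in a truth
record.

What the generator does *not* emulate: correlated landmark covariance
(noise is iid per coordinate), measurement error that scales with size,
non-linear allometry, within-population diet structure, unbalanced
designs (real data may lose a specimen), and digitizer-specific bias.
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that real stickleback data meet that model.

## Replicated experiments

`pipeline.habitat_recovery_experiment` wraps the generate → orient →
side-average → (project) → GPA → allometry → RRPP chain. Replicates use
`interaction_sd = 0` so the habitat permutation null is exact
(cell-level random effects below the specimen level would otherwise make
specimen residuals non-exchangeable for the habitat term — a property of
the test, not a bug). Fitted-vs-true habitat vectors are compared after
mapping the true pattern into the consensus frame (template
superimposition) and projecting out the similarity components that
alignment cannot estimate. Calibration runs use 1,000 replicates at 199
permutations; power/angle runs 100 replicates — sizes chosen so the full
experiment suite completes in about a minute on one CPU while keeping
binomial error on rates near 0.05 below ±0.02.

## Known limitations

- Procrustes ANOVA assumes exchangeable specimen-level residuals;
  population-level random effects are not modelled (no mixed models).
- The fluctuating-asymmetry component is untestable with single
  digitizations and absorbs digitization noise.
- The 3D KT solver assumes fixed, known rotation axes; free (spherical)
  joints and full 3DOF coupler motion are out of scope.
- Magnitude comparisons test | |u| − |v| |; the signed difference is not
  separately tested.
- The common-space construction (consensus add-back, Z = 0 embedding) is
  one defensible choice among near-equivalents; the flag is exposed.
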