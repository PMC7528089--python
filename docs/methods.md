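# Methods

## Shape representation

A lung shape is a bicubic Hermite finite-element surface mesh: quadrilateral
elements whose four corner nodes each carry 12 scalar degrees of freedom —
position `c`, the parametric tangents `∂c/∂ξ₁`, `∂c/∂ξ₂`, and the mixed
second derivative `∂²c/∂ξ₁∂ξ₂`, for `c = (x, y, z)` in millimetres.
Element interpolation is the tensor product of the four 1-D cubic Hermite
polynomials (`2t³−3t²+1`, `t³−2t²+t`, `−2t³+3t²`, `t³−t²`); local corners
are ordered (0,0), (1,0), (0,1), (1,1) with ξ₁ fastest. Derivatives are
stored per unit ξ (no arc-length scaling): since every subject shares one
topology, the statistics only ever compare like with like.

The coordinate frame is right-handed: +x towards the subject's left,
+y posterior→anterior, +z caudal→cranial.

Five surface labels partition the elements: `left_lung`, `right_lung`,
`left_oblique_fissure`, `right_oblique_fissure`, `horizontal_fissure`.
A shape vector concatenates all nodal DoFs node-major; the full-description
fixture topology (`reference_topology()`) has 225 nodes and hence 2700
parameters per subject.

## Template topology

The built-in template idealises each lung as a closed surface of
revolution (ellipsoid-like cross-section, smoothly blended asymmetric
apical/basal semi-heights standing in for the diaphragm dome), with the
poles closed by *collapsed rings*: one node per circumferential column,
all at the pole position with vanishing circumferential tangent, so every
element keeps four distinct node ids while the surface remains watertight.
This construction necessarily has slightly fewer elements than nodes —
unlike a pole-sharing quad sphere — so the default counts (left lung 36
nodes/30 elements; right 42/36; plus 24 fissure-sheet nodes) approximate
rather than reproduce a classic 35/44 + 50/62 anatomical template; node
and element counts are properties of whatever topology is loaded, and any
mesh satisfying the JSON schema is accepted.

Fissures are open quad-grid sheets defined by analytic slanted/horizontal
patch functions with a mild sinusoidal dome so they are not planar.
Fissure nodes are independent of lung-surface nodes.

## Mesh fitting

The fit minimises `T(u) = Σ γ‖z(ξ) − z_d‖² + ∫ g(u(ξ)) dξ` over all nodal
DoFs. Because projection sites depend on the geometry, the solver
alternates:

1. project every data point onto the nearest element *of its own surface
   label* (a KD-seeded damped Newton on the squared distance, with a
   deterministic lowest-(element, ξ) tie-break and a 1-D step fallback
   where the collapsed pole edges make the Hessian singular);
2. with projections frozen, solve one symmetric positive-definite linear
   system per spatial coordinate for all DoFs.

Both half-steps decrease `T`, so the outer loop is monotone.

**Smoothness penalty.** `g` is a Sobolev-type quadratic form — weights
(w₁, w₂, w_c) on the squared first, second and mixed parametric
derivatives, integrated by 4×4 Gauss–Legendre quadrature — and measures
*deformation*, i.e. it is evaluated on the difference between the fitted
DoFs and the template's (configurable back to an absolute penalty).
Defaults are w₁ = 0.1, w₂ = w_c = 0.01. These matter: the data term only
constrains the surface's normal direction, so with a near-zero penalty the
nodal parameterisation slides tangentially and data-starved DoFs (mixed
derivatives, pole nodes) swing freely between subjects — fatal for
cross-subject statistics even though the *surface* fit looks perfect. The
template-referenced penalty anchors those DoFs at their generic values
instead of flattening them.

**Initialisation.** The template is first translated and scaled to the
cloud's centroid and RMS size (`initial_similarity`), so the deformation
penalty is measured from a comparable reference; rotation is left to the
downstream Procrustes step.

**Iteration budget.** `FitConfig` defaults to at most 10 outer iterations
(tolerance 1e−3 mm on the RMSE change). Cohort runs use the 2-iteration
profile `pipeline.COHORT_FIT_CONFIG`: the first solve inherits the
template-projection correspondence, the second refines it, and further
re-projection rounds only allow more tangential sliding.

Per-point weights γ default to 1 and are exposed for fissure up-weighting.

## Alignment

Generalized Procrustes alignment estimates each subject's similarity
transform from *positions only* (derivatives would mix units), then applies
it to the full 12-DoF vector: positions by `αRx + T`, derivative DoFs by
`αR`. Rotation is the SVD/Kabsch solution with reflection guard; scale,
when enabled (size-exclusive model), is the centroid-size ratio. The
consensus is re-estimated as the arithmetic mean of the aligned vectors;
in the size-exclusive model it is centred at the origin and normalised to
unit centroid size each iteration (the pre-shape convention — rescaling an
off-origin mean moves its centroid and the iteration never settles).
The first shape bootstraps the reference; convergence is a 1e−6 relative
change of the consensus, at most 100 iterations.

## Shape model and scores

Aligned shape vectors are column-stacked (parameters × subjects), centred
about the cohort mean, and factorised by thin SVD. Modes are the left
singular vectors, sign-fixed so each mode's largest-magnitude loading is
positive; mode variances are `σ²/(N−1)` — the sample-covariance
eigenvalues, verified against a dense eigendecomposition oracle in the
tests. A centred N-column matrix has rank at most N−1; trailing
numerical-noise modes are masked by a relative singular-value threshold.
Subject scores are centred projections divided by each mode's training SD,
so training scores have unit sample SD and `mode_shape(l, w)` with
w = ±2.5 reproduces the ±2.5 SD visualisation protocol. Mode selection
takes the smallest m whose cumulative variance percentage reaches a
configurable cutoff. Leave-one-out stability refits the model N times and
reports per-mode |cosine| to the full-cohort mode plus variance-fraction
deltas.

## Association statistics

Per mode: Pearson correlation (p from the t transform on n−2 df) and
simple OLS (slope plus signed R) against age, BMI and lung volume — whole
cohort and within each sex — and Welch's t (Welch–Satterthwaite df) for
the F/M contrast; one-way ANOVA over any user-supplied grouping column.
α = 0.05 per test with no multiplicity correction by default
(Benjamini–Hochberg available as an option). A permutation Pearson p-value
is provided as an independent check of the parametric p.

## Synthetic cohort

The generator defines the study conditions. Covariates: age from a
truncated normal 53 ± 22 y on [20, 93]; BMI 24.7 ± 2.7 truncated below 30
(the exclusion threshold); sex Bernoulli with P(F) = 49/83; lung volume by
sex, 6.81 ± 1.16 L (M) and 4.84 ± 0.85 L (F), floored at 2 L.

Per subject, deformations are applied to the template in a fixed order,
each through an exact chain rule on all 12 DoFs (Jacobian for the
tangents, Jacobian plus Hessian bilinear term for the mixed derivative):

1. isotropic scaling to the drawn target volume (volume is computed by the
   divergence theorem over the closed lung surfaces, so the scaled mesh
   hits the target exactly; subsequent deformations perturb it slightly
   and the recorded covariate is the target);
2. apical taper: y (and x at half strength) scaled by `1 + g·L_age·z̃`
   with z̃ the normalised height, g = 0.004/year of effective age SD —
   older subjects taper towards the apex;
3. fissure displacement: the horizontal fissure translates basally at
   0.3 mm per year of effective age SD (a calibration choice, not a
   literature value) and the oblique fissures rotate posteriorly about
   their lung's mediolateral axis at 0.08°/year;
4. BMI-linked uniform antero-posterior scaling, 0.6 %/(kg/m²) about the
   cohort BMI mean;
5. a smooth random quadratic-polynomial displacement field rescaled to an
   exact 1.0 mm nodal RMS.

Effects 2 and 3 share one scalar *age loading*: the standardised (post-
truncation) age signal plus Gaussian noise sized so that the population
correlation between loading and age is exactly the configured target,
−0.75. The loading, BMI deviation and volume scale are returned with each
subject, which is what makes end-to-end parameter-recovery tests possible.
Point clouds are regular ξ-grid surface samples (5 per element edge by
default, ≈1900 points/subject) with 1.0 mm isotropic Gaussian noise and
per-point surface labels.

What the generator does *not* emulate: real segmentation artefacts
(anisotropic, spatially correlated error, missing fissure segments),
anatomical asymmetries beyond the idealised geometry, nonlinear covariate
interactions, and posture/gravity effects. Passing recovery tests
therefore demonstrate that the pipeline's machinery is correct and
unbiased under its stated noise model — not that effect sizes of this
magnitude are detectable in clinical CT.

## Numerical choices and degenerate inputs

- Projection seeds come from an 8×8 ξ-grid per element; exact ties
  (coincident samples at shared corners and collapsed poles) resolve to
  the lowest (element id, ξ) within a 1e−6 mm window, which keeps fitting
  exactly equivariant under rigid motion of data + template.
- Newton projection falls back to its grid seed whenever refinement fails
  to improve the distance (logged, not fatal).
- A rank-deficient fitting system with all smoothing weights zero raises
  an error advising positive smoothing.
- All-identical cohorts yield a valid zero-variance model; projection onto
  zero-variance modes returns 0; leave-one-out on such cohorts reports
  NaN cosines (flagged undefined).
- All randomness derives from a single integer seed via spawned
  substreams; same seed ⇒ byte-identical covariates, meshes and clouds.

## Problem sizes

Default analysis scale: 83 subjects, 102-node/76-element template,
~1900-point clouds, two-iteration fits; a full cohort pipeline (fit, both
alignments, both models, scores, associations) runs in well under a
minute on one core. The acceptance script averages several regenerated
cohorts; the test suite's recovery check sweeps 20 seeds at n = 83.

## Known limitations

- The collapsed-pole construction leaves the surface only C0 across pole
  edges; curvature statistics near the apex/base poles are template
  artefacts.
- Fitting assumes clouds are pre-labeled per surface; no automatic
  fissure/lung classification is provided.
- Out-of-sample subjects are scored after the same GPA convention
  (a single similarity fit to the mean), not by re-running the group
  alignment.
- The CLI's `run` command requires one cloud file per subject named by
  subject id; DICOM/NIfTI handling and segmentation are out of scope.
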