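# Methods

## Coordinate conventions

All world coordinates are RAS millimetres; voxel indices are 0-based and a
voxel contains the world point of its centre. Group analysis assumes one
shared template lattice whose midsagittal plane is x = 0 and whose x extent
is even, so voxel centres pair off symmetrically about the midline and the
hemispheric flip is an exact array reversal along the first index axis. The
flip projects all content to the right hemisphere with union semantics where
reflected-left and original-right content overlap; this mirrors the usual
lesion-mapping convention and assumes lesions and deficits are distributed
symmetrically across hemispheres. Registration into the template is out of
scope: the pipeline accepts data already on the common grid, or applies a
supplied displacement field (nearest-neighbour for masks and labels, linear
for scalar images — the resampling scheme is this package's choice).

## Trajectory model

A trajectory is the straight entry→target segment. Its mask is a *capsule*:
all voxels whose centre lies within r = (diameter/2)·voxel_size of the
segment, inclusive comparison, with hemispherical caps at both ends (default
diameter 10 voxels). Rounded rather than flat ends were chosen because the
capsule is the simplest fully specified reading and is exactly checkable
against a brute-force voxel predicate; the ≤ comparison makes the mask
closed under reflection. Target-point classification looks up the atlas
label at the containing voxel and falls back to the modal non-zero label
within 3 mm (ties to the smaller label id) — a deterministic stand-in for
the manual review a human rater would apply to points the atlas leaves
unlabelled; beyond that radius the point is reported "unclassified" rather
than guessed.

## VLSM

Mass-univariate OLS of the outcome on [1, lesion indicator, covariates] at
every voxel covered by ≥ 5 subjects (min_coverage, the field's customary
floor), one-tailed t on the lesion coefficient with df = n − p, z as the
standard-normal quantile of 1 − p. Binary outcomes are dummy coded and run
through the same linear model — the classical VLSM formulation — rather
than a per-voxel logistic fit. The default tail is "greater" (lesion
presence associated with the adverse outcome); the emitted z maps are
signed. Implementation detail: all per-voxel regressions share every
regressor except the lesion column, so the map is computed in one pass via
Frisch–Waugh–Lovell partialling; this is algebraically identical to
independent per-voxel OLS (verified to 1e-8 against a naive oracle) and
makes a 450-subject, 30k-voxel map take milliseconds. Degenerate lesion
columns (no variance after partialling) yield NaN and a warning count
instead of aborting. Bonferroni (α/N over analyzed voxels) is the only
family-wise correction offered; permutation and cluster-extent inference
are deliberately out of scope.

Type-I calibration is checked with permuted outcomes. Voxel-wise tests in
one permutation share that permutation's outcome vector and are therefore
positively correlated; the pooled p<0.05 fraction is over-dispersed relative
to a binomial over (permutations × voxels) draws. Because the variance of a
mean of correlated Bernoulli indicators is bounded by the single-draw
variance, the binomial 99% band is applied at the number of independent
permutations (500), which is valid and conservative.

## Fast-marching segmentation

Hemorrhage segmentation mimics the seeded semi-automatic workflow: the user
marks seed voxels in the bleed, a front expands with intensity-similarity
speed F(v) = 1/(1 + ((I(v) − Ī_seed)/σ)²), and the first-arrival time T
solves |∇T| = 1/F by a heap-ordered first-order upwind scheme on the
6-connected lattice (6- vs 26-connectivity is unspecified in the workflow
this emulates; 6 was fixed and the oracle bound below is stated for it).
Arrival is in voxel-edge units. The mask is {T ≤ threshold} restricted to
the seed-connected component. Defaults: σ = 100 intensity units (half-speed
at 100 HU-like units of contrast, suited to a bright bleed on CT-like
images) and threshold 10 (a unit-speed front crosses ten voxels), pinned by
a phantom test: Dice ≥ 0.90 against a known bright ellipsoid at 5σ contrast
with additive noise (measured: 1.00). Correctness is bounded against an
independent Dijkstra oracle (edge weight = mean reciprocal speed of the
incident voxels): T_fmm ≤ T_dijkstra + c_max/2 (upwind relaxation can only
undercut the lattice path; the endpoint term comes from edge-averaged
costs) and T_dijkstra ≤ √3·T_fmm + c_max (the 3D L1/L2 lattice gap).
Significance is *inclusive* at 0.5 ml: the workflow's prose says "> 0.5 ml"
but its reported volume range starts exactly at 0.5, so ≥ was chosen and is
flagged here. Manual mask correction is replaced by an optional override
input; there is no interactive editing.

## Cohort statistics

Chi-squared is Pearson's X² without Yates continuity correction — the only
dialect that reproduces the published table's printed values from its own
counts (e.g. the basal-ganglia 2×2 [[30,50],[84,286]] → 7.61). The printed
frame-vs-robot X² (0.07) does not match its own counts (0.048 uncorrected,
0.02 corrected) and is treated as a typo, not a check. Kruskal–Wallis uses
the tie-corrected H. The logistic risk model is fitted by Newton-type IRLS
(statsmodels) with Wald per-coefficient p values; Nagelkerke's R² is
computed from the fitted and null log-likelihoods. Complete separation is
reported as a non-converged fit with a warning rather than an exception.
All tests are two-sided at α = 0.05 except the VLSM t, which is one-tailed.

## Synthetic cohort generator

The generator defines the study conditions for every test; it emulates a
450-patient biopsy series:

- **Template/atlas**: a 64³, 2 mm isotropic grid; the head is an ellipsoid
  with semi-axes (55, 62, 50) mm; the atlas carries frontal, parietal,
  temporal, occipital, insular, cerebellar, brainstem and basal-ganglia
  surrogates (the basal ganglia split into anterior and posterior labels;
  the posterior label is the eloquent surrogate), all mirror-symmetric. It
  is a geometric surrogate, not a real template/atlas pair — downloading
  external atlases would break the self-contained test contract, and the
  analyses only need the symmetry and mm geometry.
- **Covariates**: age ~ N(58.3, 19.2) truncated to (1, 100); sex 47% f;
  51% robot-assisted; histology and target-region mixes follow the
  emulated series (47.6% high-grade glioma, 25% basal ganglia, ...).
- **Trajectories**: entries are jittered burr-hole zones on a 1.02× scalp
  shell — precoronal for the frontal corridor (frontal, basal-ganglia,
  insular targets), parietal boss for parietal/temporal/occipital,
  paramedian suboccipital for cerebellum/brainstem — reproducing the three
  clinical corridors and, in particular, frontal approaches to deep
  targets. Cortical targets are constrained to normalized head-depth
  r² ≤ 0.85 (lesions are parenchymal, not pial). Resulting mean length
  44 mm (series: 49.7 ± 19.3).
- **Hemorrhage model**: logit P(BBH) = b₀ + 0.022·age + 0.749·[basal
  ganglia] + 0.45·[HGG]; b₀ is calibrated by bisection against a fixed
  200k Monte-Carlo covariate draw so the marginal rate is 0.18, making the
  whole generator a pure function of (spec, seed). β_hgg is not reported
  by the emulated analysis beyond significance; 0.45 encodes a moderate
  univariate effect.
- **Volumes**: lognormal(μ=−0.60, σ=1.20) truncated below 0.5 ml (only
  significant bleeds are recorded), giving a mean significant volume of
  1.90 ml. The source reports "1.9 ± 19.0" once as a median and once as a
  mean; the generator calibrates the mean and notes the ambiguity.
- **Symptoms**: symptomatic iff volume > 5 ml or the bleed is eloquent
  (posterior basal-ganglia target with intralesional or mixed location);
  sensorimotor deficit for eloquent bleeds, reduced vigilance above 10 ml,
  revision above 5.5 ml, persistent deficit for sensorimotor or revised
  cases. Yields ≈3.7% symptomatic and ≈2.9% sensorimotor marginally.
- **Masks**: hemorrhage masks are voxel-count-exact (sorted-distance
  selection under an ellipsoidal metric at the target and/or a distal
  peritrajectory band), so mask volume matches the record to within one
  voxel and bleeds concentrate at the distal end of the trajectory.

What the generator does *not* emulate: realistic CT/MR intensities (only
the segmentation phantom has intensity structure), registration error,
spatial correlation between histology and location (available as a stress
flag, off by default), hemispheric asymmetries, and partial-volume or
motion artefacts. Passing tests therefore demonstrate correctness of the
analysis machinery under the generating model, not robustness to real
imaging noise.

## Planted-effect recovery: what is attainable

With the planted effect sizes (β_bg = 0.749, n = 450), a voxel that
perfectly tags the basal-ganglia subgroup carries exactly the group-level
association — X² ≈ 7.6, i.e. |z| ≈ 2.8. A Bonferroni threshold over the
~30–50k analyzed trajectory voxels demands z ≈ 4.8; per-voxel coverage
(5–100 of the ~112 deep-target subjects) dilutes power further. The
trajectory-vs-hemorrhage map is therefore evaluated at its published
uncorrected p < 0.05 thresholding; measured mean sensitivity for the
planted region over 20 cohorts is ≈ 0.28 (and 0 with Bonferroni) — the
corresponding acceptance test documents the shortfall rather than hiding
it. The hemorrhage-vs-sensorimotor map, whose planted association is
near-deterministic, does survive Bonferroni and localizes predominantly
(≈ 70–90% of suprathreshold voxels) inside the eloquent label.

## Problem sizes

Default analyses run on the 64³/2 mm grid with n = 450 cohorts; recovery
metrics average 20 seeds in the test suite and 5 in the acceptance script;
generator calibration uses 50 and 30 seeds respectively; logistic recovery
uses one n = 20,000 cohort; the segmentation oracle runs on 20³ instances
and the phantom on 24³. These sizes were chosen so each property is
measured with comfortable statistical margin while the whole suite stays
interactive.

## Known limitations

- The linear-model VLSM on binary outcomes is the classical formulation
  but not a calibrated probability model per voxel.
- Bonferroni is conservative under the strong spatial correlation of
  capsule masks; no permutation-based FWE alternative is provided.
- The axis profile retains axial fractions in [−0.2, 1.2] (bleeds extend
  past the needle tip); 24 bins by default — the bin count of the figure
  this emulates is unknown. The cross-section's in-plane orientation is an
  arbitrary deterministic basis; only rotation-invariant summaries of it
  should be interpreted.
- `cohort_summary` reports no mortality row (the record schema carries no
  mortality field).
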