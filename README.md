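# bbhmap

Voxel-based analysis of hemorrhage risk in stereotactic brain biopsies.

Stereotactic biopsy of intracranial lesions carries a well-known complication:
biopsy-related hemorrhage (BBH), radiographically common (~18% of cases) but
symptomatic in only a few percent. Beyond patient- and tumor-level predictors
(age, high-grade glioma), *where* the needle goes matters — deep targets in
the basal ganglia bleed more often, and bleeds in eloquent deep gray matter
are the ones that cause sensorimotor deficits. `bbhmap` implements the full
voxel-based evaluation of this problem for neurosurgical imaging researchers:
from per-patient trajectory coordinates and hemorrhage masks in a common
template space to frequency maps, voxel-wise lesion-symptom maps, cohort
statistics and a hemorrhage profile along a standardized trajectory. A
synthetic-cohort generator with known ground truth makes every stage testable
without any imaging data.

## What it computes

- **Trajectory mapping** — entry→target segments rasterized as capsule masks
  (default diameter 10 voxels), flipped to the right hemisphere about the
  midsagittal plane, and stacked into overlap frequency maps.
- **Voxel-based lesion-symptom mapping (VLSM)** — at every voxel $v$ covered
  by at least 5 subjects, the outcome $y$ is regressed on the lesion
  indicator $\ell_v$ (plus optional covariates) by OLS:
  $y_i = \beta_0 + \beta_1 \ell_{iv} + \gamma^\top c_i + \varepsilon_i$,
  with a one-tailed $t$ statistic on $\hat\beta_1$ ($\mathrm{df}=n-p$), a
  matching standard-normal $z$, and Bonferroni control
  $\alpha/N_\text{voxels}$ across the analyzed voxels. Exposed as a
  scikit-learn-style estimator (`VoxelLesionSymptomMapper`).
- **Hemorrhage segmentation** — seed-based fast marching: front speed
  $F(v) = 1/\bigl(1 + ((I(v)-\bar I_\text{seed})/\sigma)^2\bigr)$, first
  arrival from a heap-ordered upwind Eikonal solver, thresholded and
  restricted to the seed component; volumetry in ml with an inclusive 0.5 ml
  significance cutoff; intralesional/extralesional classification.
- **Cohort statistics** — Pearson chi-squared (no continuity correction),
  tie-corrected Kruskal–Wallis, Pearson correlation, and binary logistic
  regression with Wald tests and Nagelkerke
  $R^2 = \frac{1-\exp(2(LL_0-LL)/n)}{1-\exp(2 LL_0/n)}$
  (`HemorrhageRiskModel`, scikit-learn interface), plus the standard
  patients/hemorrhage summary tables.
- **Trajectory-axis profile** — each hemorrhage voxel mapped into its
  subject's trajectory frame (axial fraction 0 = entry, 1 = target; radial
  mm) and pooled into axial-frequency and cross-sectional histograms.
- **Synthetic cohorts** — a midline-symmetric template and atlas surrogate,
  patients with realistic covariates, burr-hole-zone entries, a logistic
  hemorrhage model (log-odds 0.022 per year of age, 0.749 for basal-ganglia
  targets), lognormal volumes and eloquence-driven symptom rules.

## Worked example

```python
import pandas as pd
from bbhmap import (CohortSpec, HemorrhageRiskModel, VoxelLesionSymptomMapper,
                    flip_to_right, generate_cohort, generate_template,
                    rasterize_trajectory, threshold_map)
from bbhmap.synthetic import records_to_frame

template, atlas = generate_template()          # 64^3 grid, 2 mm isotropic
records = generate_cohort(CohortSpec(seed=1), atlas)
df = records_to_frame(records)

X = pd.DataFrame({"age": df.age,
                  "bg": (df.target_region == "basal_ganglia").astype(int),
                  "hgg": (df.histology == "HGG").astype(int)})
model = HemorrhageRiskModel().fit(X, df.bbh.astype(int))

masks = [flip_to_right(rasterize_trajectory(r.trajectory, atlas)) for r in records]
vlsm = VoxelLesionSymptomMapper().fit(masks, df.bbh.astype(float).to_numpy())
```

Printing the cohort marginals, the fitted coefficients and the map summary
gives:

```
cohort: n=450, hemorrhage rate 20.2%, symptomatic 4.2%
mean trajectory length 43.0 mm, mean hemorrhage volume 1.89 ml
beta_age = +0.022 (p = 0.002)
beta_bg = +0.830 (p = 0.001)
beta_hgg = +0.267 (p = 0.270)
Nagelkerke R2 = 0.071
VLSM: 34254 voxels analyzed, 3878 suprathreshold (p<0.05 uncorrected), peak z = 4.50
```

Read: this particular seed drew a 20.2% hemorrhage rate (the generator is
calibrated to 18% on average); the refitted logistic model recovers the
planted age (0.022/year) and basal-ganglia (0.749 log-odds; here 0.830 with
n=450 sampling noise) effects; the trajectory-vs-hemorrhage VLSM finds its
suprathreshold voxels in the deep frontal corridor with a peak z of 4.5.

The same pipeline runs end to end from the command line:

```bash
bbhmap run-all --seed 1 --outdir out/        # or --config run.yaml
bbhmap generate --n-patients 450 --seed 1 --outdir data/ --write-masks
bbhmap segment --image ct.nii.gz --seeds-csv seeds.csv --out bbh.nii.gz
```

`out/` then holds the cohort CSV, NIfTI frequency and t/z/p maps, TSV tables,
PNG figures and a JSON report.

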