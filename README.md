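# lungshape

Statistical shape modeling of the human lungs and their lobar fissures.

Lung shape changes with age — the chest wall stiffens, the lung tissue
loses elastic recoil, and the lobar fissures shift — and a quantitative
description of *normal* shape and its variability is the prerequisite for
using shape as a biomarker. This package implements the full statistical
shape analysis pipeline for bi-lung + fissure surfaces:

1. **Bicubic Hermite surface meshes** — each node carries 12 degrees of
   freedom (position, the two first parametric derivatives and the mixed
   second derivative, per spatial direction), so a coarse mesh encodes
   surface curvature and a shared topology gives point correspondence
   across subjects.
2. **Template fitting** — a generic mesh is geometry-fitted to each
   subject's labeled surface point cloud by minimising
   `T(u) = Σ γ ‖z(ξ₁,ξ₂) − z_d‖² + ∫ g(u(ξ)) dξ`,
   a weighted point-to-surface misfit plus a Sobolev smoothness penalty on
   the surface deformation, solved by alternating point projection with a
   linear least-squares update of all nodal DoFs.
3. **Generalized Procrustes alignment** — rotation/translation (and,
   optionally, centroid-size scaling: `S̄ = αRS + T`) are removed against
   an evolving consensus, producing a *size-inclusive* and a
   *size-exclusive* dataset.
4. **PCA shape model** — aligned shape vectors are column-stacked,
   centered, and factorised by thin SVD (`S = UΣVᵀ`); modes are the left
   singular vectors, mode variances `λ_l = σ_l²/(N−1)`, variance explained
   `v_m = 100·Σ₁^m λ_k / Σ λ_k`, and mode shapes `m_l(w) = S̄₀ + w·u_l`
   (w in SD units, e.g. ±2.5 SD for visualisation).
5. **Association statistics** — per-mode SD-unit scores are tested against
   age, sex, BMI and imaged lung volume with Pearson/OLS, Welch's t and
   one-way ANOVA at α = 0.05.

Because no imaging data ships with the package, a first-class **synthetic
cohort generator** emulates the study material: idealised closed lung
surfaces with fissure sheets, covariate distributions matching the study
cohort (n = 83, age 53 ± 22 y, BMI 24.7 ± 2.7, 49 F/34 M expected, lung
volume 6.81 ± 1.16 L in males and 4.84 ± 0.85 L in females), and planted,
covariate-linked deformations (size↔sex, apical taper and basal fissure
shift↔age, antero-posterior change↔BMI) whose recovery every downstream
stage is tested against.

## Worked example

The numbered drivers under `analysis/` run the study pipeline on the
default synthetic cohort (seed 20) and write their tables to `results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_fit_meshes.py
python 05_associations.py
```

prints

```
simulated 83 subjects (52 F / 31 M)
fitted 83 subjects; RMSE 1.02 +/- 0.04 mm (cloud noise 1.0 mm)
         model  top_volume_mode  volume_r  top_age_mode  age_r_aligned
size-inclusive                1     0.973             2         -0.700
size-exclusive                4     0.124             1         -0.751
```

Read: the fitted surfaces sit at the 1 mm noise floor of the synthetic
"segmentations"; when lung size is left in the model (size-inclusive),
mode 1 is essentially lung volume (r = 0.97) and the age deformation
surfaces as mode 2; once size is removed (size-exclusive), no mode tracks
volume any more and the planted age effect becomes mode 1, recovered at
r = −0.75 against age — the generator's planted population value. The
same structure as shifting every mode index down by one when moving from
the size-inclusive to the size-exclusive model.

The library surface mirrors the pipeline:

```python
from lungshape import (GeneratorConfig, generate_cohort, fit_mesh, gpa,
                       assemble, build_ssm, score_table, association_table)
```

and a `lungshape` CLI exposes `simulate`, `fit`, `align`, `build-ssm`,
`project`, `mode-shape`, `associate` and `run` subcommands over the same
code.

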