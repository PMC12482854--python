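# Methods

This note documents the models, parameter choices and numerical decisions
behind `atnquant`, and what the synthetic phantoms do and do not establish
about behaviour on real data.

## Pipeline overview

A quantification run takes a 3-D PET volume and an integer parcellation
(132 structures, Neuromorphometrics naming) on — or rigidly registerable
to — a common grid, and produces regional SUVr tables, composite-mask SUVr
converted to Centiloid (CL) or CenTauRz (CTRz), native and ICV-normalized
volumes, a HAVAs neurodegeneration probability, and the categorical A/T₂/N
panel. All geometry runs through NIfTI voxel-to-world affines (RAS world,
0-based voxel indices); no axis order is ever assumed.

## Registration and resampling

PET-to-anatomy registration is rigid (6 parameters: rotations in degrees
about the world axes, translations in mm, rotation centred on the fixed
image's intensity centre of mass). The similarity metric is normalized
mutual information, (H(A)+H(B))/H(A,B), from a 48-bin joint histogram over
all overlapping voxels — no stochastic sampling, so the procedure is fully
deterministic. Optimisation is derivative-free Powell over a two-level
Gaussian pyramid (downsampling 4× then 2×, smoothing σ = 2 and 1 voxels,
at most 20 Powell iterations per level, parameter tolerance 10⁻³).
Initialisation aligns intensity centres of mass, giving a capture range
comfortably beyond ±10 mm / ±10°; on noiseless smooth phantoms the
recovered parameters are within ~0.05 mm / 0.05° of truth (the test suite
enforces 0.5 mm / 0.5° over 20 seeded perturbations).

The anatomy-to-template affine is accepted as a precomputed input
(identity when data are already in template space); the package does not
perform template registration. The rigid and affine maps are composed
into a single matrix so the PET is interpolated exactly once (trilinear;
labels always nearest-neighbour, which preserves the label value set).
One test demonstrates that the chained two-pass resample has strictly
larger error against an analytic ground truth than the composed
single-pass resample.

## Regional statistics and SUVr

Region means are computed by vectorized accumulation and are tested for
exact equality against a naive per-voxel loop. Voxels with NaN or
negative uptake are excluded from means and reported per region; labels
present in the dictionary but absent from the volume are kept as
flagged zero-count rows. Composite regions — the whole-cerebellum and
cerebellar-GM references, the Centiloid cortical mask and the CenTauR
meta-temporal mask — use pooled-voxel (volume-weighted) means, equivalent
to computing the mean over the union mask; the alternative (unweighted
average of region means) was rejected to match mask-based SUVr
conventions. SUVr is reported for grey-matter structures only: the
bundled dictionary has 132 entries of which 122 are GM, so a full
parcellation yields a 122-row SUVr table. The reference region's own
pooled SUVr is 1 by construction.

The bundled label dictionary (`data/labels_v1.csv`) is an artifact of
this package: 98 bilateral cortical structures, 24 subcortical/other GM,
4 WM and 6 CSF entries with sequential ids. Any table with `id,name,
tissue` columns can replace it; composite masks are defined by structure
*name* (`data/masks_v1.json`) and resolved against whatever dictionary is
loaded. The Centiloid cortical mask default (bilateral
frontal/cingulate/parietal/lateral-temporal structures plus precuneus) is
likewise an overridable package default; the meta-temporal tau mask
(entorhinal, amygdala, parahippocampal, fusiform, inferior and middle
temporal, temporal pole) is fixed by the CenTauR convention. A
data-driven mask can be derived with
`select_discriminative_structures`, which ranks structures by absolute
Cohen's d with pooled SD (default) or Mann-Whitney AUC between two
cohorts of SUVr tables; the criterion choice is a package decision, since
the originating protocol does not name one.

## Partial-volume correction

The optional PVC is an iterative region-based scheme (iterative Yang):
each pass rebuilds a piecewise-constant image from the current per-region
means (background is its own region), blurs it with the Gaussian PSF
(FWHM in mm, default 6), and multiplies the *observed* image by the
synthetic/blurred ratio. It is a self-contained substitute for
super-resolution PVC methods, off by default. On a two-region phantom
blurred at 6 mm the region means return to within 2% of truth after 5
iterations, with strictly decreasing error over the first three; total
uptake is conserved to well under 1% per iteration when the labelled
regions tile the field of view (with unlabelled background, blurred
signal spills outside the mask and the global sum is not conserved —
this is a property of the phantom, not a defect of the scheme).

## Calibration

- **Level-1 (Centiloid).** Anchors are the group means of the young-CN
  amyloid-negative and AD-dementia SUVr distributions; the conversion is
  the exact algebraic expansion CL = 100(S − m_yCN)/(m_AD − m_yCN).
  Unrounded coefficients map the anchors to exactly 0 and 100; the
  bundled printed coefficients (4 decimals) reproduce 100 CL at the AD
  anchor within 0.01.
- **Level-2 (other amyloid tracers).** OLS of PiB SUVr on tracer SUVr,
  composed with the PiB map by exact algebra — no refit, so the composed
  map equals pib(regression(x)) at machine precision.
- **CenTauR Level-1.** OLS of pipeline FTP SUVr on published SUVr_CTR,
  reported in the inverse form SUVr_CTR = (S − a)/b.
- **Regression choice.** Simple OLS throughout (the validity criteria
  are stated for OLS fits); a Deming regression with configurable
  variance ratio is available for sensitivity analyses. R² is the
  squared Pearson correlation, identical to 1 − SSE/SST for simple OLS.
- **Validity check.** Computed-vs-published OLS must have slope in
  [0.98, 1.02] and R² > 0.98; the ±2 intercept bound is a CL-scale
  criterion and is computed for CTRz but enforced only for CL.
- **Bundled constants.** All five amyloid and six tau conversion rows
  are stored exactly as printed (4 decimals) in
  `data/conversions_v1.json` and used as-is by `convert()`. The five
  non-FTP tau equations derive from the CenTauR project's published
  tracer equations and cannot be refit from data bundled here; they are
  carried as constants only.

## Staging

Boundary semantics (each a deliberate reading of the printed
inequalities, ties resolved toward the inclusive side):

| Quantity | Rule | Boundary |
|---|---|---|
| CL (AMYPAD) | <10 A−, 10–30 A_inter, >30 A+ | 10 and 30 → A_inter |
| CL (binary) | ≥24.1 A+ | 24.1 → A+ |
| CTRz | <2 T2− | 2 → T2+ |
| HAVAs | >0.5 N+ | 0.5 → N− |

A missing modality yields `not_assessed` for its axis; the pipeline runs
with amyloid only, tau only, or neither (volumetry + N).

### HAVAs surrogate

The neurodegeneration probability is produced by a **surrogate** model,
branded `surrogate-v1` in all outputs. It z-scores the bilateral
hippocampal, amygdalar and inferior-lateral-ventricular ICV fractions
against a synthetic age-linear normative table (hippocampus
0.0050 − 1.5·10⁻⁵/yr from age 40, SD 6·10⁻⁴; amygdala 0.0022 − 6·10⁻⁶/yr,
SD 3·10⁻⁴; inferior lateral ventricle 0.0006 + 1.2·10⁻⁵/yr, SD 4·10⁻⁴ —
magnitudes chosen once to be realistic for adult ICV fractions), then
maps the signed average z (atrophy and ventricular enlargement both
positive) through a logistic with scale 2. By construction it returns
0.5 at the normative means for any age, exceeds 0.9 at 3 SD of combined
atrophy, and is monotone in each input. It does **not** reproduce the
published lifespan-model parameters; a real model can be supplied as a
JSON file of the same schema (`load_havas_model`).

## Synthetic phantoms

`make_label_phantom` tessellates all 132 structures as jittered
ellipsoids on a lattice in a 64³ grid at 2 mm (template-size 181×217×181
at 1 mm available via `SpaceSpec`); `make_pet_phantom` builds
piecewise-constant uptake, blurs with a Gaussian PSF and adds Gaussian
noise. Calibration cohorts default to the development-cohort scale (77
young controls, 152 dementia) at the published anchor means with
within-group SD 0.1 — a single pooled value of realistic magnitude for
amyloid SUVr cohorts. All generators draw from seeded PCG64 streams, one
named stream per component, so outputs are bit-reproducible and fixtures
are independent.

What the phantoms establish: arithmetic correctness (means, pooling,
SUVr, conversions), registration capture and single-interpolation
behaviour, PVC convergence on piecewise-constant signal, and the full
CSV/JSON/report plumbing. What they do not establish: performance on
real anatomy (no cortical folding, no realistic PSF anisotropy, no
scatter/attenuation artifacts, no inter-subject anatomical variability),
and realistic HAVAs values — phantom blob volumes are much larger than
real hippocampal ICV fractions, so the demo's N axis sits at the floor
of the surrogate's range. Claims about real-data concordance are
outside this package's scope.

## Problem sizes and determinism

The default test grid is 64³ at 2 mm, chosen so the complete suite
(including 20 seeded registration recoveries and the PVC convergence
phantoms) runs in a couple of minutes on one CPU. Registration is
deterministic by construction; every stochastic fixture takes an explicit
seed; two pipeline runs with the same config and seed produce
byte-identical CSV/JSON outputs (timestamps are confined to logs).

## Known limitations

- Rigid registration only; the anatomy-to-template affine must be
  supplied (or be identity). No nonlinear registration, motion
  correction or dynamic PET.
- The bundled dictionary's id↔name assignment is conventional, not the
  official Neuromorphometrics table; users substituting real
  parcellations should supply their own CSV and verify mask resolution.
- The PVC substitute assumes a stationary isotropic Gaussian PSF.
- HAVAs values from `surrogate-v1` are not comparable to published
  HAVAs probabilities.
- ICV is estimated as the total labelled volume when not supplied; with
  a parcellation that does not cover the full intracranial space this
  underestimates ICV and inflates ICV fractions.
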