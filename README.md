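# atnquant

Regional quantification of amyloid- and tau-PET with harmonized Centiloid /
CenTauRz scaling and A/T₂/N biomarker staging — plus a synthetic phantom
generator that makes the whole pipeline testable without any scanner data.

`atnquant` is aimed at neuroimaging researchers who have a co-registered PET
volume and an anatomical parcellation (132 structures following the
Neuromorphometrics naming protocol) and want, per subject:

- **SUVr tables** for the 122 grey-matter structures, normalized to the
  whole cerebellum (amyloid) or cerebellar grey matter (tau);
- **Centiloid (CL)** and **CenTauRz (CTRz)** values from composite cortical
  masks, via bundled cross-tracer linear conversions;
- **volumetry** (native mm³ and intracranial-volume fractions);
- a categorical **A/T₂/N panel** with documented thresholds.

## The quantification model

For a structure *r* with mean uptake $\bar{u}_r$ and a reference region
*R* (pooled-voxel mean $\bar{u}_R$), the standardized uptake value ratio is

$$\mathrm{SUVr}_r = \bar{u}_r / \bar{u}_R .$$

Composite masks (reference regions and the CL/CTRz cortical masks) use
volume-weighted, pooled-voxel means over the union of their member
structures. The Centiloid scale anchors PiB SUVr linearly between the
young-control mean ($m_{yCN} = 0.9659$) and the AD-dementia mean
($m_{AD} = 1.8972$):

$$\mathrm{CL} = 100 \cdot \frac{\mathrm{SUVr} - m_{yCN}}{m_{AD} - m_{yCN}}
  \;\;\Rightarrow\;\; \mathrm{CL} = 107.3768\,\mathrm{SUVr} - 103.7152 .$$

Other amyloid tracers (FBP, FBB, FTM, NAV) reach the CL scale through a
Level-2 step: OLS regression of paired PiB-vs-tracer SUVr, composed with
the PiB map by exact algebra. Tau tracers reach CTRz through the analogous
CenTauR calibration over the meta-temporal mask (entorhinal, amygdala,
parahippocampal, fusiform, inferior/middle temporal, temporal pole); all
eleven tracer equations are bundled as a versioned data file.

Staging: A− / A_inter / A+ at 10 and 30 CL (AMYPAD mode; a binary 24.1 CL
mode is also provided), T₂± at CTRz 2, N± at HAVAs probability 0.5. The
bundled HAVAs neurodegeneration model is an explicitly-branded surrogate
(see `docs/methods.md`).

## Worked example

```bash
atnquant phantom --preset atn-demo --seed 7 --out demo/
atnquant quantify --labels demo/labels.nii.gz \
    --amyloid-pet demo/amyloid_pet.nii.gz --tau-pet demo/tau_pet.nii.gz \
    --amyloid-tracer PiB --tau-tracer FTP --out out/
cat out/report.txt
```

prints (numbers produced by the demo phantom: elevated neocortical amyloid
uptake and meta-temporal tau uptake, cerebellum pinned to 1.0):

```
A/T2/N quantification report
============================

Amyloid (A)              CL = 54.3924         A+   [CL<10 A- | 10-30 A_inter | >30 A+]
Tau (T2)                 CTRz = 7.4836        T2+   [CTRz<2 T2-]
Neurodegeneration (N)    HAVAs = 0.0000       N-   [p>0.5 N+]
```

The demo's cortical-to-cerebellum uptake ratio (≈1.5 after blurring) maps
to 54.4 CL through the PiB equation, and the meta-temporal tau contrast to
7.5 CTRz — an A+/T₂+ profile. The HAVAs probability is ~0 because the
geometric phantom's blob volumes are far larger than real
hippocampal/amygdalar ICV fractions; see the methods note. `out/` also
contains `amyloid_suvr.csv` and `tau_suvr.csv` (122 grey-matter rows
each), `volumes.csv` (132 rows), `panel.json` and a provenance log.

The same pipeline is available as a library:

```python
import atnquant as aq

labels = aq.read_label_volume("demo/labels.nii.gz")
pet = aq.read_volume("demo/amyloid_pet.nii.gz")
stats = aq.region_stats(pet, labels)
masks = aq.load_masks()
ref = aq.resolve_mask("whole_cerebellum", masks, labels.dictionary)
suvr = aq.suvr_table(stats, ref, labels.dictionary)   # 122 rows
cortex = aq.resolve_mask("centiloid_cortex", masks, labels.dictionary)
cl = aq.convert("PiB", aq.composite_suvr(stats, cortex, ref))
```

PET volumes that are not yet on the label grid can be registered with
`rigid_register` (normalized-mutual-information, multi-resolution) and
brought over with a **single** interpolation via
`compose_transforms` + `resample_once` (CLI: `--register`, with
`--assume-registered` to bypass).

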