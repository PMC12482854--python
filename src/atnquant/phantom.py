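"""Synthetic phantom and cohort generation.

Every other module is testable offline against these generators: label
phantoms tessellate the full 132-structure dictionary into jittered
ellipsoidal blobs on a lattice; PET phantoms are piecewise-constant uptake
maps blurred with a Gaussian PSF plus additive Gaussian noise; calibration
cohorts draw SUVr values around the published Level-1 anchors (young-CN
mean 0.9659, AD-dementia mean 1.8972) at the development-cohort sample
sizes (77 young controls, 152 dementia patients).

Determinism: NumPy's PCG64 via ``default_rng`` with one named stream per
component (labels / uptake-noise / cohorts / pairs / rigid), so a fixed
seed gives bit-identical output and changing one fixture does not shift the
others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imgio import (ImageVolume, LabelDictionary, LabelVolume, SpaceSpec,
                    load_label_dictionary, write_label_volume, write_volume)
from .spatial import RigidTransform

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "DEFAULT_GRID",
    "make_label_phantom",
    "make_pet_phantom",
    "make_calibration_cohort",
    "make_paired_tracer_data",
    "uptake_from_tissue",
    "random_rigid",
    "make_atn_demo",
]

# stream ids keep the per-component RNGs independent
_STREAM_LABELS = 0
_STREAM_NOISE = 2
_STREAM_COHORT = 3
_STREAM_PAIRS = 4
_STREAM_RIGID = 5

DEFAULT_GRID = SpaceSpec.isotropic((64, 64, 64), 2.0)

# Published Level-1 anchor means (young-CN A- and AD-dementia PiB SUVr).
ANCHOR_YCN = 0.9659
ANCHOR_AD = 1.8972


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of a synthetic phantom."""

    grid: SpaceSpec = DEFAULT_GRID
    psf_fwhm: float = 0.0      # mm
    noise_sd: float = 0.0      # uptake units
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Level-1 calibration cohort: two Gaussian SUVr groups.

    Defaults are the study conditions: anchor means 0.9659 / 1.8972 and
    the development-cohort sizes (77 young CN, 152 dementia).
    """

    n_ycn: int = 77
    n_ad: int = 152
    m_ycn: float = ANCHOR_YCN
    m_ad: float = ANCHOR_AD
    sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_ycn < 2 or self.n_ad < 2:
            raise ValueError("need >=2 subjects per group")
        if self.sd < 0:
            raise ValueError("within-group sd must be non-negative")


def make_label_phantom(spec: PhantomSpec | None = None,
                       dictionary: LabelDictionary | None = None
                       ) -> LabelVolume:
    """Tessellate every dictionary label as a jittered ellipsoid blob.

    Blobs sit on a regular lattice (one cell per structure, jittered
    centres and radii); painting never overwrites an earlier blob, and the
    result is checked to contain every dictionary id.  Deterministic for a
    fixed seed.
    """
    spec = spec or PhantomSpec()
    dictionary = dictionary or load_label_dictionary()
    ids = dictionary.ids
    n = len(ids)
    shape = np.array(spec.grid.shape)
    cells = int(np.ceil(n ** (1.0 / 3.0)))
    cell_size = shape / cells
    if cell_size.min() < 4.0:
        raise ValueError(
            f"grid {tuple(shape)} too small for {n} labels "
            f"(cell size {cell_size.min():.1f} voxels < 4)")

    rng = np.random.default_rng([spec.seed, _STREAM_LABELS])
    labels = np.zeros(tuple(shape), dtype=np.int32)
    # lattice cells in C order; first n cells hold the structures
    cell_idx = [(i, j, k) for i in range(cells) for j in range(cells)
                for k in range(cells)][:n]
    half = cell_size.min() / 2.0
    for lid, (i, j, k) in zip(ids, cell_idx):
        center = (np.array([i, j, k]) + 0.5) * cell_size \
            + rng.uniform(-1.5, 1.5, size=3)
        radii = rng.uniform(0.45 * half, 0.8 * half, size=3)
        lo = np.maximum(np.floor(center - radii).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(center + radii).astype(int) + 2, shape)
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        d = ((sub - center) / radii) ** 2
        inside = d.sum(axis=1) <= 1.0
        pts = sub[inside]
        current = labels[pts[:, 0], pts[:, 1], pts[:, 2]]
        free = current == 0
        labels[pts[free, 0], pts[free, 1], pts[free, 2]] = lid
    present = set(np.unique(labels)) - {0}
    missing = set(ids) - present
    if missing:
        raise RuntimeError(f"phantom generation lost labels {sorted(missing)}")
    return LabelVolume(labels=labels, affine=spec.grid.affine,
                       dictionary=dictionary, space="template")


def make_pet_phantom(labels: LabelVolume, uptake_map: dict,
                     psf_fwhm: float = 0.0, noise_sd: float = 0.0,
                     seed: int = 0) -> ImageVolume:
    """Piecewise-constant uptake -> Gaussian PSF blur -> additive noise."""
    present = set(np.unique(labels.labels)) - {0}
    missing = present - set(uptake_map)
    if missing:
        raise ValueError(f"uptake_map missing labels: {sorted(missing)}")
    if any(v < 0 for v in uptake_map.values()):
        raise ValueError("uptake values must be non-negative")
    nmax = int(labels.labels.max()) + 1
    lut = np.zeros(nmax, dtype=np.float64)
    for lid, v in uptake_map.items():
        if lid < nmax:
            lut[lid] = v
    img = lut[labels.labels]
    if psf_fwhm > 0:
        voxel = np.sqrt((labels.affine[:3, :3] ** 2).sum(axis=0))
        sigma = psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel
        img = ndimage.gaussian_filter(img, sigma)
    if noise_sd > 0:
        rng = np.random.default_rng([seed, _STREAM_NOISE])
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return ImageVolume(data=img, affine=labels.affine, space=labels.space)


def uptake_from_tissue(dictionary: LabelDictionary, gm: float = 1.4,
                       wm: float = 0.7, csf: float = 0.2,
                       overrides: dict | None = None) -> dict:
    """Uptake map by tissue class, with optional per-name overrides.

    ``overrides`` maps a case-insensitive name substring to an uptake value
    (e.g. {"cerebellum": 1.0} pins the whole cerebellum to 1.0).
    """
    base = {"GM": gm, "WM": wm, "CSF": csf}
    out = {i: base[t] for i, _, t in dictionary.entries}
    for key, v in (overrides or {}).items():
        hit = [i for i, name, _ in dictionary.entries
               if key.lower() in name.lower()]
        if not hit:
            raise KeyError(f"override {key!r} matches no structure")
        for i in hit:
            out[i] = v
    return out


def make_calibration_cohort(spec: CohortSpec | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two Level-1 groups; sd = 0 gives the anchors exactly."""
    spec = spec or CohortSpec()
    if spec.sd == 0:
        return (np.full(spec.n_ycn, spec.m_ycn),
                np.full(spec.n_ad, spec.m_ad))
    rng = np.random.default_rng([spec.seed, _STREAM_COHORT])
    return (rng.normal(spec.m_ycn, spec.sd, size=spec.n_ycn),
            rng.normal(spec.m_ad, spec.sd, size=spec.n_ad))


def make_paired_tracer_data(true_slope: float, true_intercept: float,
                            n: int, noise_sd: float = 0.0, seed: int = 0,
                            x_range: tuple[float, float] = (0.8, 2.5)
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (tracer SUVr, PiB SUVr) lists with a known linear relation."""
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    rng = np.random.default_rng([seed, _STREAM_PAIRS])
    x = rng.uniform(*x_range, size=n)
    y = true_slope * x + true_intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return x, y


def random_rigid(seed: int = 0, max_translation: float = 10.0,
                 max_rotation: float = 10.0,
                 center: tuple[float, float, float] = (0.0, 0.0, 0.0)
                 ) -> RigidTransform:
    """A seeded rigid perturbation within the given capture range."""
    rng = np.random.default_rng([seed, _STREAM_RIGID])
    rot = tuple(rng.uniform(-max_rotation, max_rotation, size=3))
    tra = tuple(rng.uniform(-max_translation, max_translation, size=3))
    return RigidTransform(rotations=rot, translations=tra, center=center)


def make_atn_demo(outdir: str | Path, seed: int = 7,
                  psf_fwhm: float = 4.0, noise_sd: float = 0.02) -> dict:
    """Write the atn-demo preset: labels, amyloid + tau PET, truth.json.

    The amyloid phantom has elevated neocortical uptake (amyloid-positive
    pattern, cerebellum pinned to 1.0); the tau phantom concentrates signal
    in the meta-temporal structures.  truth.json records the generating
    uptake values and the noise/PSF settings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dictionary = load_label_dictionary()
    labels = make_label_phantom(PhantomSpec(seed=seed), dictionary)

    amyloid_uptake = uptake_from_tissue(
        dictionary, gm=1.8, wm=1.3, csf=0.3, overrides={"cerebellum": 1.0})
    tau_uptake = uptake_from_tissue(
        dictionary, gm=1.1, wm=0.8, csf=0.3,
        overrides={"cerebellum": 1.0, "entorhinal": 1.6, "amygdala": 1.6,
                   "parahippocampal": 1.6, "fusiform": 1.6,
                   "temporal gyrus": 1.6, "temporal pole": 1.6})
    amyloid = make_pet_phantom(labels, amyloid_uptake, psf_fwhm, noise_sd,
                               seed=seed)
    tau = make_pet_phantom(labels, tau_uptake, psf_fwhm, noise_sd,
                           seed=seed + 1)

    write_label_volume(labels, outdir / "labels.nii.gz")
    write_volume(amyloid, outdir / "amyloid_pet.nii.gz")
    write_volume(tau, outdir / "tau_pet.nii.gz")
    truth = {
        "seed": seed, "psf_fwhm_mm": psf_fwhm, "noise_sd": noise_sd,
        "grid": {"shape": list(labels.labels.shape),
                 "voxel_mm": list(np.sqrt(
                     (labels.affine[:3, :3] ** 2).sum(axis=0)))},
        "amyloid_uptake": {str(k): v for k, v in amyloid_uptake.items()},
        "tau_uptake": {str(k): v for k, v in tau_uptake.items()},
    }
    with open(outdir / "truth.json", "w") as f:
        json.dump(truth, f, indent=1)
    return truth
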