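"""Volume and label-dictionary I/O.

All geometry in this package is expressed through the NIfTI voxel-to-world
affine (RAS world convention, 0-based voxel indices).  Scalar volumes are
written as 32-bit float, integer label volumes as unsigned 16-bit.  The
bundled label dictionary follows the Neuromorphometrics naming protocol:
132 structures, of which 122 are grey matter (the SUVr reporting set) and
10 are white matter or CSF.  The specific id-to-name assignment is a
versioned artifact of this package (``labels_v1.csv``) and can be replaced
by any table with the same ``id,name,tissue`` columns.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "LabelDictionary",
    "SpaceSpec",
    "TEMPLATE_SPEC",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "load_label_dictionary",
    "load_masks",
]

TISSUE_CLASSES = ("GM", "WM", "CSF")


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("atnquant").joinpath("data", name))


@dataclass(frozen=True)
class SpaceSpec:
    """A sampling grid: shape, voxel size and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float) -> "SpaceSpec":
        """Axis-aligned RAS grid centred on the world origin."""
        shape = tuple(int(s) for s in shape)
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
        return cls(shape=shape, voxel_size=(voxel_mm,) * 3, affine=aff)


def _template_spec() -> SpaceSpec:
    # MNI template grid; world origin at voxel (90, 126, 72) as in SPM.
    aff = np.eye(4)
    aff[:3, 3] = (-90.0, -126.0, -72.0)
    return SpaceSpec(shape=(181, 217, 181), voxel_size=(1.0, 1.0, 1.0), affine=aff)


TEMPLATE_SPEC = _template_spec()


@dataclass
class ImageVolume:
    """A 3-D scalar field (PET uptake or anatomical intensity) plus affine."""

    data: np.ndarray
    affine: np.ndarray
    space: str = "native"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or not np.all(np.isfinite(self.affine)):
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def grid(self) -> SpaceSpec:
        return SpaceSpec(shape=self.data.shape, voxel_size=self.voxel_size,
                         affine=self.affine)


@dataclass(frozen=True)
class LabelDictionary:
    """Maps integer structure ids to names and GM/WM/CSF tissue classes."""

    entries: tuple  # of (id, name, tissue)
    version: str = "custom"

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate label id(s): {dup}")
        for i, name, tissue in self.entries:
            if i <= 0:
                raise ValueError(f"label id must be positive, got {i} ({name})")
            if tissue not in TISSUE_CLASSES:
                raise ValueError(
                    f"unknown tissue class {tissue!r} for label {i} ({name}); "
                    f"expected one of {TISSUE_CLASSES}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[int]:
        return [e[0] for e in self.entries]

    @property
    def gm_ids(self) -> list[int]:
        return [e[0] for e in self.entries if e[2] == "GM"]

    def name(self, label_id: int) -> str:
        return self._by_id()[label_id][0]

    def tissue(self, label_id: int) -> str:
        return self._by_id()[label_id][1]

    def id_of(self, name: str) -> int:
        for i, n, _ in self.entries:
            if n == name:
                return i
        raise KeyError(f"no structure named {name!r} in dictionary")

    def _by_id(self) -> dict:
        return {i: (n, t) for i, n, t in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.entries), columns=["id", "name", "tissue"])


def load_label_dictionary(path: str | Path | None = None) -> LabelDictionary:
    """Load a label dictionary from CSV/TSV, or the bundled default.

    The table needs ``id``, ``name`` and ``tissue`` columns; tissue must be
    one of GM, WM, CSF.  Duplicate ids are rejected.
    """
    version = "custom"
    if path is None:
        path = _data_path("labels_v1.csv")
        version = "labels_v1"
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label dictionary not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"id", "name", "tissue"} - set(df.columns)
    if missing:
        raise ValueError(f"label dictionary {path} missing columns: {sorted(missing)}")
    entries = tuple(
        (int(r.id), str(r.name), str(r.tissue)) for r in df.itertuples(index=False)
    )
    return LabelDictionary(entries=entries, version=version)


@dataclass
class LabelVolume:
    """Integer-labelled parcellation volume; 0 is background."""

    labels: np.ndarray
    affine: np.ndarray
    dictionary: LabelDictionary
    space: str = "native"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label volume, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("label values must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.dictionary.ids)
        if unknown:
            raise ValueError(
                f"label value(s) {sorted(unknown)} present in volume but absent "
                f"from dictionary")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def grid(self) -> SpaceSpec:
        vs = tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))
        return SpaceSpec(shape=self.labels.shape, voxel_size=vs, affine=self.affine)


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape} in {path}")
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"non-finite affine in {path}")
    return img, affine


def read_volume(path: str | Path) -> ImageVolume:
    """Read a scalar 3-D NIfTI-1 volume, applying header scaling."""
    img, affine = _load_nifti(path)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return ImageVolume(data=data, affine=affine)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a scalar volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def read_label_volume(path: str | Path,
                      dictionary: LabelDictionary | None = None) -> LabelVolume:
    """Read an integer label volume; validates labels against the dictionary."""
    if dictionary is None:
        dictionary = load_label_dictionary()
    img, affine = _load_nifti(path)
    raw = np.asanyarray(img.dataobj)
    data = np.rint(np.asarray(raw)).astype(np.int32)
    return LabelVolume(labels=data, affine=affine, dictionary=dictionary)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write an integer label volume as uint16 NIfTI-1."""
    if vol.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed uint16 range")
    img = nib.Nifti1Image(vol.labels.astype(np.uint16), vol.affine)
    nib.save(img, str(path))


def load_masks(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load named composite-mask definitions (structure-name lists).

    Defaults to the bundled ``masks_v1.json``: whole cerebellum and
    cerebellar-GM reference regions, the CenTauR meta-temporal mask
    (entorhinal, amygdala, parahippocampal, fusiform, inferior/middle
    temporal, temporal pole) and a default Centiloid cortical mask.
    """
    if path is None:
        path = _data_path("masks_v1.json")
    with open(path) as f:
        return json.load(f)
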