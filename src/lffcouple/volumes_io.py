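"""Volumetric and tabular I/O plus the shared grid data types.

All modules exchange data through three containers defined here:

* :class:`BoldRun` -- one subject's 4D BOLD-like time series with grid
  metadata and TR;
* :class:`MaskSet` -- brain / grey-matter / white-matter / CSF binary
  masks on the same grid;
* :class:`SubjectRecord` -- subject id, group label, covariates and
  motion parameters.

Volumes are NIfTI-1 (optionally gzipped) via nibabel; tables are TSV via
pandas.  Voxel indexing is 0-based, masks and data must share shape
exactly (no resampling), statistic maps store NaN outside the brain and
4D data store zeros outside the brain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "MCI", "AD")
GENDERS = ("M", "F")

COHORT_COLUMNS = ["subject_id", "group", "age", "gender", "education", "gmv"]
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

MIN_TIMEPOINTS = 16

__all__ = [
    "BoldRun",
    "MaskSet",
    "SubjectRecord",
    "read_bold",
    "write_bold",
    "read_map",
    "write_map",
    "read_mask_set",
    "write_mask_set",
    "read_cohort_table",
    "write_cohort_table",
    "read_motion",
    "write_motion",
    "GROUPS",
]


@dataclass
class BoldRun:
    """One subject's 4D BOLD-like volume.

    ``data`` has axes (x, y, z, t); units are arbitrary.  ``affine`` is
    the 4x4 voxel-to-world transform carried through to any file output.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} volumes, got {self.data.shape[3]}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contain non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        """A copy of this run carrying new voxel data on the same grid."""
        return BoldRun(
            data=data,
            tr_seconds=self.tr_seconds,
            affine=self.affine,
            subject_id=self.subject_id,
        )


@dataclass
class MaskSet:
    """Brain / GM / WM / CSF binary masks on a common grid.

    Invariants (enforced at construction): the tissue masks are disjoint
    subsets of the brain mask and every mask is nonempty.
    """

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("brain", "gm", "wm", "csf"):
            m = np.asarray(getattr(self, name))
            if m.ndim != 3:
                raise ValueError(f"mask {name!r} must be 3D, got {m.ndim}D")
            setattr(self, name, m.astype(bool))
        shapes = {m.shape for m in (self.brain, self.gm, self.wm, self.csf)}
        if len(shapes) != 1:
            raise ValueError(f"masks have mismatching shapes: {shapes}")
        for name in ("brain", "gm", "wm", "csf"):
            if not getattr(self, name).any():
                raise ValueError(f"mask {name!r} is empty")
        for name in ("gm", "wm", "csf"):
            if (getattr(self, name) & ~self.brain).any():
                raise ValueError(f"mask {name!r} is not a subset of the brain mask")
        for a, b in (("gm", "wm"), ("gm", "csf"), ("wm", "csf")):
            if (getattr(self, a) & getattr(self, b)).any():
                raise ValueError(f"masks {a!r} and {b!r} overlap")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain.shape

    def tissue(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class SubjectRecord:
    """Demographics, covariates and motion for one subject.

    ``gmv`` is total grey-matter volume in decilitres; ``motion`` is the
    t x 6 realignment-parameter table (3 translations, 3 rotations) or
    None when not yet attached.
    """

    subject_id: str
    group: str
    age: float
    gender: str
    education: float
    gmv: float
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for subject {self.subject_id!r}; "
                f"expected one of {GROUPS}"
            )
        if self.gender not in GENDERS:
            raise ValueError(
                f"unknown gender {self.gender!r} for subject {self.subject_id!r}"
            )
        if not self.gmv > 0:
            raise ValueError(f"gmv must be positive, got {self.gmv}")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.ndim != 2 or self.motion.shape[1] != 6:
                raise ValueError("motion must be a t x 6 array")


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_bold(
    path: str | Path,
    tr_seconds: float | None = None,
    subject_id: str | None = None,
) -> BoldRun:
    """Read a 4D NIfTI-1 file into a :class:`BoldRun`.

    TR is taken from the header's fourth zoom (pixdim[4]); an explicit
    ``tr_seconds`` overrides the header with a logged warning.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_seconds is not None:
        if header_tr > 0 and not np.isclose(header_tr, tr_seconds):
            logger.warning(
                "TR override: header says %.4gs, config says %.4gs; using config",
                header_tr,
                tr_seconds,
            )
        tr = tr_seconds
    elif header_tr > 0:
        tr = header_tr
    else:
        raise ValueError(f"TR absent from header of {path} and not supplied")
    return BoldRun(
        data=data,
        tr_seconds=tr,
        affine=img.affine,
        subject_id=subject_id if subject_id is not None else path.name.split(".")[0],
    )


def write_bold(run: BoldRun, path: str | Path) -> Path:
    """Write a :class:`BoldRun` as NIfTI-1, recording TR in pixdim[4]."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(run.data), run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D statistic map; returns (values, affine)."""
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D map, got {data.ndim}D: {path}")
    return data, img.affine


def write_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D statistic map as 32-bit float NIfTI-1.

    NaN marks out-of-mask voxels and is allowed; an all-NaN map is
    rejected as empty.
    """
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected 3D map, got {values.ndim}D")
    if np.isnan(values).all():
        raise ValueError("empty map: all values are NaN")
    path = Path(path)
    img = nib.Nifti1Image(values.astype(np.float32), np.asarray(affine, dtype=float))
    nib.save(img, path)
    return path


_MASK_FILES = {"brain": "brain", "gm": "gm", "wm": "wm", "csf": "csf"}


def write_mask_set(masks: MaskSet, directory: str | Path, affine: np.ndarray | None = None) -> Path:
    """Write the four masks as ``<directory>/{brain,gm,wm,csf}.nii.gz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    for name, stem in _MASK_FILES.items():
        img = nib.Nifti1Image(masks.tissue(name).astype(np.uint8), aff)
        nib.save(img, directory / f"{stem}.nii.gz")
    return directory


def read_mask_set(directory: str | Path) -> MaskSet:
    """Read masks written by :func:`write_mask_set`; invariants are re-validated."""
    directory = Path(directory)
    loaded = {}
    for name, stem in _MASK_FILES.items():
        candidates = [directory / f"{stem}.nii.gz", directory / f"{stem}.nii"]
        for cand in candidates:
            if cand.exists():
                loaded[name] = np.asarray(nib.load(cand).dataobj) > 0
                break
        else:
            raise FileNotFoundError(f"mask file for {name!r} not found in {directory}")
    return MaskSet(**loaded)


# ---------------------------------------------------------------------------
# Tables


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort TSV into subject records.

    Requires columns ``subject_id, group, age, gender, education, gmv``;
    group labels are validated against HC/MCI/AD and duplicate subject
    ids are rejected.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {sorted(set(dup))}")
    return [
        SubjectRecord(
            subject_id=row.subject_id,
            group=row.group,
            age=float(row.age),
            gender=row.gender,
            education=float(row.education),
            gmv=float(row.gmv),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort_table(records: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "education": [r.education for r in records],
            "gmv": [r.gmv for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_motion(path: str | Path) -> np.ndarray:
    """Read a t x 6 motion-parameter TSV."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion table missing columns: {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a t x 6 array")
    path = Path(path)
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path
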