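"""Masked 3-D scalar volumes and aligned cohort stacks.

A :class:`VolumeGrid` is one subject's scalar map (an FA-like image) on a
voxel lattice together with a binary analysis mask; a :class:`CohortStack`
is an ordered set of grids on one common lattice plus a per-subject
covariate table.  All downstream statistics operate on the flattened
in-mask voxel matrix (``n_subjects x n_voxels``), so the containers also
provide the round trip between volumes and matrices.

NIfTI-1 is the on-disk format (via nibabel); volumes are written as 32-bit
floats and promoted to 64-bit in memory.  The affine is carried through
unchanged — no registration or resampling happens here.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GridCompatibilityError, ValidationError

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "education")


@dataclasses.dataclass
class VolumeGrid:
    """One masked 3-D scalar lattice.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (dimensionless FA in [0, 1] for real FA maps;
        unrestricted for score maps).
    voxel_size : tuple of float
        Physical voxel edge lengths in mm, all strictly positive.
    mask : ndarray of bool, same shape as ``data``
        Analysis mask; values at ``mask == False`` are ignored everywhere
        downstream.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine, carried through unchanged.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if self.mask is None:
            self.mask = np.isfinite(self.data) & (self.data != 0)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.data.shape:
            raise GridCompatibilityError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_mask(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Flattened vector of in-mask data values."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(np.asarray(data, dtype=np.float64), self.voxel_size,
                          self.mask.copy(), self.affine.copy())

    def with_masked_values(self, values: np.ndarray, fill: float = np.nan) -> "VolumeGrid":
        """Scatter a flat in-mask vector back onto the lattice."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.n_mask,):
            raise GridCompatibilityError(
                f"expected {self.n_mask} masked values, got {values.shape}"
            )
        data = np.full(self.shape, fill, dtype=np.float64)
        data[self.mask] = values
        return VolumeGrid(data, self.voxel_size, self.mask.copy(), self.affine.copy())

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and bool(np.array_equal(self.mask, other.mask)))

    def require_compatible(self, other: "VolumeGrid", what: str = "volume") -> None:
        if self.shape != other.shape or not np.allclose(self.voxel_size, other.voxel_size):
            raise GridCompatibilityError(
                f"{what}: grid mismatch (shape {other.shape} vs {self.shape}, "
                f"voxel size {other.voxel_size} vs {self.voxel_size})"
            )


@dataclasses.dataclass
class CohortStack:
    """Aligned stack of volumes plus a covariate table.

    ``covariates`` has one row per volume with columns
    ``subject_id, age, sex, education`` (sex coded ``F``/``M`` or 0/1).
    ``role_label`` records how the group is used: ``reference``,
    ``test_control``, or ``patient``.
    """

    volumes: list[VolumeGrid]
    covariates: pd.DataFrame | None = None
    role_label: str = "reference"

    def __post_init__(self) -> None:
        if len(self.volumes) == 0:
            raise ValidationError("a cohort needs at least one volume")
        grid0 = self.volumes[0]
        for i, v in enumerate(self.volumes[1:], start=1):
            grid0.require_compatible(v, what=f"cohort volume {i}")
            if not np.array_equal(grid0.mask, v.mask):
                raise GridCompatibilityError(
                    f"cohort volume {i} mask differs; use stack_cohort() to intersect masks"
                )
        if self.covariates is not None:
            self.covariates = self.covariates.reset_index(drop=True)
            if len(self.covariates) != len(self.volumes):
                raise ValidationError(
                    f"{len(self.covariates)} covariate rows for {len(self.volumes)} volumes"
                )

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def grid(self) -> VolumeGrid:
        """Representative grid (geometry only)."""
        return self.volumes[0]

    @property
    def mask(self) -> np.ndarray:
        return self.volumes[0].mask

    def as_matrix(self) -> np.ndarray:
        """In-mask data as an ``(n_subjects, n_voxels)`` float64 matrix."""
        return np.stack([v.masked_values() for v in self.volumes])

    def covariate_matrix(self) -> np.ndarray:
        """Numeric (age, sex01, education) matrix aligned with the volumes."""
        if self.covariates is None:
            raise ValidationError("cohort has no covariate table")
        return encode_covariates(self.covariates)

    def subset(self, indices: Sequence[int], role_label: str | None = None) -> "CohortStack":
        vols = [self.volumes[i] for i in indices]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[list(indices)].reset_index(drop=True)
        return CohortStack(vols, cov, role_label or self.role_label)


def encode_covariates(table: pd.DataFrame) -> np.ndarray:
    """Encode age/sex/education as a numeric matrix (sex: F=0, M=1)."""
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    sex = table["sex"]
    if sex.dtype == object:
        codes = sex.astype(str).str.upper().map({"F": 0.0, "M": 1.0})
        if codes.isna().any():
            raise ValidationError("sex column must contain only F/M (or 0/1)")
        sex = codes
    out = np.column_stack([
        table["age"].to_numpy(dtype=np.float64),
        np.asarray(sex, dtype=np.float64),
        table["education"].to_numpy(dtype=np.float64),
    ])
    if not np.all(np.isfinite(out)):
        raise ValidationError("covariate table contains missing/non-finite entries")
    return out


# ---------------------------------------------------------------------------
# I/O

def load_volume(path: str | os.PathLike, mask_path: str | os.PathLike | None = None) -> VolumeGrid:
    """Load a NIfTI volume (and optional mask) as a :class:`VolumeGrid`.

    Without an explicit mask, the default analysis mask is the set of
    finite, nonzero voxels.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O classes
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mdata = np.asanyarray(mimg.dataobj)
        if mdata.shape != data.shape:
            raise GridCompatibilityError(
                f"mask shape {mdata.shape} != image shape {data.shape}"
            )
        mask = mdata > 0
    return VolumeGrid(data, voxel_size, mask, np.asarray(img.affine))


def save_volume(grid: VolumeGrid, path: str | os.PathLike, dtype=np.float32) -> None:
    """Write a grid to NIfTI-1 (float32 on disk by default)."""
    img = nib.Nifti1Image(grid.data.astype(dtype), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, like: VolumeGrid, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), like.affine)
    img.header.set_zooms(like.voxel_size)
    nib.save(img, str(path))


def load_covariates(path: str | os.PathLike) -> pd.DataFrame:
    """Read a covariate CSV with header (subject_id, age, sex, education)."""
    table = pd.read_csv(path)
    encode_covariates(table)  # validate eagerly
    return table


def stack_cohort(paths: Sequence[str | os.PathLike],
                 covariates: pd.DataFrame | None = None,
                 mask: np.ndarray | None = None,
                 role_label: str = "reference") -> CohortStack:
    """Load >=2 congruent volumes into a :class:`CohortStack`.

    If per-subject default masks differ, their intersection is used (and
    logged) so that every retained voxel has an observation from every
    subject.  An explicit ``mask`` overrides the per-subject masks.
    """
    if len(paths) < 2:
        raise ValidationError("a cohort stack needs at least 2 volumes")
    if covariates is not None and len(covariates) != len(paths):
        raise ValidationError(
            f"{len(covariates)} covariate rows for {len(paths)} volumes"
        )
    volumes = [load_volume(p) for p in paths]
    grid0 = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        grid0.require_compatible(v, what=f"volume {paths[i]}")
    if mask is None:
        mask = np.logical_and.reduce([v.mask for v in volumes])
        if any(not np.array_equal(mask, v.mask) for v in volumes):
            logger.info("per-subject masks differ; using intersection (%d voxels)",
                        int(mask.sum()))
        if not mask.any():
            logger.warning("cohort mask intersection is empty")
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid0.shape:
            raise GridCompatibilityError(
                f"mask shape {mask.shape} != volume shape {grid0.shape}"
            )
    volumes = [VolumeGrid(v.data, v.voxel_size, mask.copy(), v.affine) for v in volumes]
    return CohortStack(volumes, covariates, role_label)


def cohort_from_arrays(arrays: Iterable[np.ndarray],
                       mask: np.ndarray,
                       voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       covariates: pd.DataFrame | None = None,
                       role_label: str = "reference") -> CohortStack:
    """Build a cohort directly from in-memory 3-D arrays on a shared mask."""
    mask = np.asarray(mask).astype(bool)
    vols = [VolumeGrid(np.asarray(a, dtype=np.float64), voxel_size, mask.copy())
            for a in arrays]
    return CohortStack(vols, covariates, role_label)
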