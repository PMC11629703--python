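"""Volume data model, NIfTI I/O and geometric mask operations.

All voxel-level quantities (lesion masks, normative seed maps, atlas
labels) live on a shared 3-D grid. World coordinates follow a RAS-like
convention: +x right, +y anterior, +z superior, with the left hemisphere
at negative x. Voxel ``(0, 0, 0)`` is centred at ``origin`` and voxel
centres advance by ``voxel_size`` mm along each axis.

Cross-volume operations require *exact* grid agreement (dims, voxel size
and origin); there is no implicit resampling. Analyses assume all inputs
were normalised to one template grid beforehand, and a silent resample
would mask registration errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class GridMismatchError(ValueError):
    """Raised when two volumes do not share dims, voxel size and origin."""


class VolumeFormatError(ValueError):
    """Raised for files that cannot be interpreted as a 3-D volume."""


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 entries, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar grid with voxel size (mm) and world origin (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        vs = _as_triple(self.voxel_size, "voxel_size")
        if min(vs) <= 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def world_coordinates(self) -> np.ndarray:
        """(n_voxels, 3) world coordinates of all voxel centres, C order."""
        grids = np.meshgrid(*(self.axis_coords(i) for i in range(3)), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def grid_compatible(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def check_grid(self, other: "Volume3D") -> None:
        if not self.grid_compatible(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.voxel_size}/{self.origin} vs "
                f"{other.shape}/{other.voxel_size}/{other.origin}"
            )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.voxel_size, self.origin)


@dataclass(frozen=True)
class BinaryMask(Volume3D):
    """A Volume3D whose values are exactly 0 or 1 (stored as uint8)."""

    def __post_init__(self):
        super().__post_init__()
        data = np.asarray(self.data)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        else:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("BinaryMask values must be exactly 0 or 1")
            data = data.astype(np.uint8)
        object.__setattr__(self, "data", data)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def flat_indices(self) -> np.ndarray:
        """Flat (C-order) indices of the voxels inside the mask."""
        return np.flatnonzero(self.data.ravel())


def as_binary_mask(vol: Volume3D) -> BinaryMask:
    return BinaryMask(vol.data, vol.voxel_size, vol.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 file into a :class:`Volume3D`.

    The affine must be a positive diagonal (axis-aligned RAS grid); rotated
    or flipped images are rejected rather than silently reoriented.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable header
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D image, got ndim={data.ndim}")
    aff = img.affine
    diag = np.diag(aff[:3, :3])
    if not np.allclose(aff[:3, :3], np.diag(diag), atol=1e-6) or np.any(diag <= 0):
        raise VolumeFormatError(f"{path}: affine is not a positive diagonal grid")
    return Volume3D(data, tuple(diag), tuple(aff[:3, 3]))


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1. Integer data round-trips bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    elif np.issubdtype(data.dtype, np.integer) and data.dtype.itemsize > 4:
        info = np.iinfo(np.int32)
        if data.size and (data.min() < info.min or data.max() > info.max):
            raise ValueError("integer data exceeds the int32 range NIfTI supports")
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    return as_binary_mask(read_volume(path))


# ---------------------------------------------------------------------------
# Mask operations


def mask_volume_ml(mask: BinaryMask) -> float:
    """Lesion volume in millilitres (voxel count x voxel volume / 1000)."""
    return mask.voxel_count * mask.voxel_volume_mm3 / 1000.0


def _ball_structure(voxel_size, radius_mm: float) -> np.ndarray:
    reach = [int(np.floor(radius_mm / vs + 1e-9)) for vs in voxel_size]
    offsets = np.meshgrid(*(np.arange(-r, r + 1) for r in reach), indexing="ij")
    dist2 = sum((off * vs) ** 2 for off, vs in zip(offsets, voxel_size))
    return dist2 <= radius_mm**2 * (1 + 1e-9)


def dilate_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Dilate by a Euclidean ball of ``radius_mm`` (anisotropy respected)."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    structure = _ball_structure(mask.voxel_size, radius_mm)
    if structure.sum() <= 1:  # radius below half the voxel width
        return mask
    out = ndimage.binary_dilation(mask.data.astype(bool), structure=structure)
    return BinaryMask(out, mask.voxel_size, mask.origin)


def hemisphere_restrict(mask: BinaryMask, side: str) -> BinaryMask:
    """Keep voxels left (x < 0) or right (x > 0) of the midline plane.

    Voxel centres exactly on x = 0 belong to neither hemisphere and are
    dropped.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    x = mask.axis_coords(0)
    keep = x < -1e-9 if side == "L" else x > 1e-9
    data = mask.data * keep[:, None, None].astype(np.uint8)
    return BinaryMask(data, mask.voxel_size, mask.origin)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    a.check_grid(b)
    return BinaryMask(np.maximum(a.data, b.data), a.voxel_size, a.origin)


def mask_intersection(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    a.check_grid(b)
    return BinaryMask(a.data * b.data, a.voxel_size, a.origin)


# ---------------------------------------------------------------------------
# Parcellation

ROI_CLASSES = ("cortical", "subcortical", "tract")
HEMISPHERES = ("L", "R", "bilateral")

ROI_TABLE_COLUMNS = ["roi_id", "name", "class", "hemisphere", "network", "cx", "cy", "cz"]


@dataclass
class Parcellation:
    """ROI registry: label volume plus a per-ROI table.

    Cortical and subcortical ROIs are stored in ``label_volume`` (0 =
    background). White matter tracts overlap each other, so they are backed
    by separate per-tract masks in ``tract_masks`` instead of labels.
    Cortical ROIs carry a Yeo-style network assignment and a unit-sphere
    centroid used by the spin permutation null.
    """

    label_volume: Volume3D
    roi_table: pd.DataFrame
    tract_masks: dict[int, BinaryMask] = field(default_factory=dict)
    tract_endpoints: dict[int, tuple[int, int]] | None = None

    def __post_init__(self):
        tab = self.roi_table.reset_index(drop=True).copy()
        missing = [c for c in ROI_TABLE_COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(f"roi_table missing columns: {missing}")
        if tab["roi_id"].duplicated().any():
            raise ValueError("duplicate roi_id in roi_table")
        bad = set(tab["class"]) - set(ROI_CLASSES)
        if bad:
            raise ValueError(f"unknown ROI classes: {bad}")
        labels = np.unique(np.asarray(self.label_volume.data))
        labels = labels[labels != 0]
        known = set(tab["roi_id"].astype(int))
        unknown = set(labels.astype(int)) - known
        if unknown:
            raise ValueError(f"labels present in volume but not in table: {unknown}")
        for rid in self.tract_masks:
            if rid not in known:
                raise ValueError(f"tract mask {rid} not in roi_table")
            self.label_volume.check_grid(self.tract_masks[rid])
        cort = tab[tab["class"] == "cortical"]
        if cort["network"].isna().any():
            raise ValueError("cortical ROIs must all have a network")
        cents = cort[["cx", "cy", "cz"]].to_numpy(dtype=float)
        if len(cents) and not np.allclose(np.linalg.norm(cents, axis=1), 1.0, atol=1e-6):
            raise ValueError("cortical centroids must have unit norm")
        self.roi_table = tab

    # -- registry helpers ---------------------------------------------------
    def roi_ids(self, roi_class: str | None = None) -> list[int]:
        tab = self.roi_table
        if roi_class is not None:
            tab = tab[tab["class"] == roi_class]
        return sorted(tab["roi_id"].astype(int))

    @property
    def cortical_ids(self) -> list[int]:
        return self.roi_ids("cortical")

    @property
    def subcortical_ids(self) -> list[int]:
        return self.roi_ids("subcortical")

    @property
    def tract_ids(self) -> list[int]:
        return self.roi_ids("tract")

    @property
    def networks(self) -> list[str]:
        nets = self.roi_table.loc[self.roi_table["class"] == "cortical", "network"]
        return sorted(nets.dropna().unique())

    def roi_row(self, roi_id: int) -> pd.Series:
        rows = self.roi_table[self.roi_table["roi_id"] == roi_id]
        if rows.empty:
            raise KeyError(f"unknown roi_id {roi_id}")
        return rows.iloc[0]

    def roi_mask(self, roi_id: int) -> BinaryMask:
        if roi_id in self.tract_masks:
            return self.tract_masks[roi_id]
        data = np.asarray(self.label_volume.data) == roi_id
        if not data.any() and roi_id not in set(self.roi_table["roi_id"]):
            raise KeyError(f"unknown roi_id {roi_id}")
        return BinaryMask(data, self.label_volume.voxel_size, self.label_volume.origin)

    def cortical_centroids(self) -> pd.DataFrame:
        tab = self.roi_table
        cort = tab[tab["class"] == "cortical"].set_index("roi_id")
        return cort[["cx", "cy", "cz"]].astype(float)

    def network_of(self, roi_id: int):
        return self.roi_row(roi_id)["network"]


def write_roi_table(parc_or_table, path) -> None:
    tab = parc_or_table.roi_table if isinstance(parc_or_table, Parcellation) else parc_or_table
    tab.to_csv(path, sep="\t", index=False)


def read_roi_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    for col in ("network", "name", "hemisphere"):
        if col in tab.columns:
            tab[col] = tab[col].where(pd.notna(tab[col]), None)
    return tab
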