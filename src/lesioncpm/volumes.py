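"""Template-grid volume data model and NIfTI I/O.

Every analysis stage in this package operates on 3D scalar or label grids
that share one template geometry ("grid").  No resampling or registration is
performed here: volumes that do not share shape, voxel size and orientation
are rejected with :class:`GridMismatchError`.  Spatial normalisation is
assumed to have happened upstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "LesionMask",
    "Parcellation",
    "ClusterSet",
    "VolumeFormatError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "overlap_volume",
    "extract_clusters",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable, non-3D or non-finite volume inputs."""


class GridMismatchError(ValueError):
    """Raised when volumes on different template grids are combined."""


def _grid_token(shape: tuple[int, ...], affine: np.ndarray) -> str:
    """Opaque identifier of a template geometry (shape + rounded affine)."""
    h = hashlib.sha1()
    h.update(np.asarray(shape, dtype=np.int64).tobytes())
    h.update(np.round(np.asarray(affine, dtype=np.float64), 6).tobytes())
    return h.hexdigest()[:16]


@dataclass
class Volume3D:
    """A 3D scalar grid with geometry.

    Parameters
    ----------
    data:
        3D array of finite values. NaN anywhere is a hard error; silent
        NaN-as-zero semantics hide upstream processing mistakes.
    affine:
        4x4 voxel-to-world matrix (NIfTI convention). Defaults to 1 mm
        isotropic identity.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume contains NaN or infinite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        zooms = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return tuple(float(z) for z in zooms)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def grid_id(self) -> str:
        return _grid_token(self.shape, self.affine)

    def same_grid(self, other: "Volume3D") -> bool:
        return self.grid_id == other.grid_id

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on this grid with different values."""
        return Volume3D(data=data, affine=self.affine.copy())


def check_same_grid(*vols: Volume3D) -> None:
    ids = {v.grid_id for v in vols}
    if len(ids) > 1:
        raise GridMismatchError(
            f"volumes live on {len(ids)} different template grids"
        )


@dataclass
class LesionMask:
    """A strictly binary lesion mask for one subject."""

    mask: Volume3D
    subject_id: str

    def __post_init__(self) -> None:
        vals = np.unique(self.mask.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise VolumeFormatError(
                f"lesion mask for {self.subject_id!r} is not binary"
            )
        if not np.any(self.mask.data):
            raise VolumeFormatError(
                f"lesion mask for {self.subject_id!r} is empty"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat voxel indices of the lesion (C order)."""
        return np.flatnonzero(self.mask.data.ravel())

    def check_within(self, brain_mask: Volume3D) -> None:
        check_same_grid(self.mask, brain_mask)
        outside = np.logical_and(self.mask.data > 0, brain_mask.data <= 0)
        if np.any(outside):
            raise VolumeFormatError(
                f"lesion {self.subject_id!r} has {int(outside.sum())} voxels "
                "outside the brain mask"
            )


@dataclass
class Parcellation:
    """Integer-labelled parcellation; 0 is background."""

    labels: Volume3D
    roi_ids: list[int]
    roi_names: list[str] | None = None
    hemisphere: list[str] | None = None  # per-ROI, "L" or "R"

    def __post_init__(self) -> None:
        lab = self.labels.data
        if np.any(lab < 0) or np.any(lab != np.round(lab)):
            raise VolumeFormatError("parcellation labels must be nonnegative integers")
        present = set(np.unique(lab.astype(np.int64))) - {0}
        missing = set(self.roi_ids) - present
        if missing:
            raise VolumeFormatError(f"roi_ids absent from label volume: {sorted(missing)}")
        if any(i <= 0 for i in self.roi_ids):
            raise VolumeFormatError("roi ids must be positive")
        if self.hemisphere is not None:
            if len(self.hemisphere) != len(self.roi_ids):
                raise VolumeFormatError("hemisphere tags must match roi_ids length")
            if not set(self.hemisphere) <= {"L", "R"}:
                raise VolumeFormatError("hemisphere tags must be 'L' or 'R'")

    def roi_mask(self, roi_id: int) -> Volume3D:
        return self.labels.with_data((self.labels.data == roi_id).astype(np.float64))

    def rois_in_hemisphere(self, hemi: str) -> list[int]:
        if self.hemisphere is None:
            raise ValueError("parcellation carries no hemisphere tags")
        return [r for r, h in zip(self.roi_ids, self.hemisphere) if h == hemi]


# connectivity structure elements: face / face+edge / face+edge+corner
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterSet:
    """Disjoint connected components of a binary volume."""

    clusters: list[np.ndarray]  # each (k, 3) voxel coordinates
    connectivity: int = 26
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def total_voxels(self) -> int:
        return sum(self.sizes)


def read_volume(path) -> Volume3D:
    """Read a NIfTI volume (.nii / .nii.gz; gzip handled transparently)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions"
        )
    return Volume3D(data=np.asarray(data, dtype=np.float64), affine=img.affine)


def write_volume(vol: Volume3D, path) -> None:
    """Write a NIfTI-1 volume; binary-valued data is stored as uint8."""
    data = vol.data
    vals = np.unique(data)
    if vals.size and np.all(np.isin(vals, (0.0, 1.0))):
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float64)
    img = nib.Nifti1Image(out, vol.affine)
    nib.save(img, str(path))


def overlap_volume(a: Volume3D, b: Volume3D, threshold: float = 0.0) -> int:
    """Number of voxels where the binary mask ``a`` is 1 and ``b`` > threshold."""
    check_same_grid(a, b)
    avals = np.unique(a.data)
    if not np.all(np.isin(avals, (0.0, 1.0))):
        raise VolumeFormatError("overlap_volume: first argument must be binary")
    return int(np.count_nonzero((a.data > 0) & (b.data > threshold)))


def extract_clusters(v: Volume3D, connectivity: int = 26) -> ClusterSet:
    """Connected-component decomposition of a binary volume.

    An empty foreground yields an empty ClusterSet, not an error.
    """
    vals = np.unique(v.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise VolumeFormatError("extract_clusters expects a binary volume")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labelled, n = ndimage.label(v.data > 0, structure=_STRUCTS[connectivity])
    clusters = []
    for i in range(1, n + 1):
        coords = np.argwhere(labelled == i)
        clusters.append(coords)
    return ClusterSet(clusters=clusters, connectivity=connectivity, grid_shape=v.shape)
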