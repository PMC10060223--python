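"""Lesion disconnection scores.

A subject's disconnection score for a ROI is the sum of that ROI's
connectivity-map values over the voxels covered by the subject's lesion
mask: a lesion that cuts through voxels carrying many streamlines to the
ROI (high AC values) yields a high score.  FC maps are signed (Fisher z)
and the masked sum is taken as-is — no absolute value — so FC scores can be
negative.  The per-cohort result is a subjects x ROIs matrix plus lesion
volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity_maps import ConnectivityAtlas
from .volumes import LesionMask, Volume3D, VolumeFormatError, check_same_grid

__all__ = [
    "DisconnectionMatrix",
    "disconnection_score",
    "disconnection_matrix",
    "lesion_volume",
]


@dataclass
class DisconnectionMatrix:
    """Subjects x ROIs masked-sum scores, plus lesion volumes in mm^3."""

    scores: pd.DataFrame  # index: subject_id, columns: roi_id (int)
    kind: str  # AC | FC | edge_density | lesion_volume
    lesion_volumes_mm3: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("disconnection scores must be finite")
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate subject_ids in disconnection matrix")
        if self.kind == "AC" and np.any(self.scores.to_numpy() < 0):
            raise ValueError("AC disconnection scores must be nonnegative")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def roi_ids(self) -> list[int]:
        return list(self.scores.columns)

    def subset_rois(self, roi_ids: list[int]) -> "DisconnectionMatrix":
        return DisconnectionMatrix(
            scores=self.scores[list(roi_ids)].copy(),
            kind=self.kind,
            lesion_volumes_mm3=self.lesion_volumes_mm3,
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        """TSV (subjects x ROI columns) plus a JSON sidecar."""
        path = Path(path)
        self.scores.rename_axis("subject_id").to_csv(path, sep="\t")
        sidecar = {
            "kind": self.kind,
            "provenance": self.provenance,
            "lesion_volumes_mm3": (
                None
                if self.lesion_volumes_mm3 is None
                else self.lesion_volumes_mm3.to_dict()
            ),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "DisconnectionMatrix":
        path = Path(path)
        scores = pd.read_csv(path, sep="\t", index_col="subject_id")
        scores.columns = [int(c) for c in scores.columns]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        lv = sidecar.get("lesion_volumes_mm3")
        return cls(
            scores=scores,
            kind=sidecar["kind"],
            lesion_volumes_mm3=None if lv is None else pd.Series(lv),
            provenance=sidecar.get("provenance", {}),
        )


def disconnection_score(lesion: LesionMask, cmap: Volume3D) -> float:
    """Sum of map values over the lesioned voxels."""
    check_same_grid(lesion.mask, cmap)
    vals = cmap.data.ravel()[lesion.indices]
    if np.any(np.isnan(vals)):
        raise VolumeFormatError("NaN in connectivity map under the lesion mask")
    return float(vals.sum())


def disconnection_matrix(
    lesions: list[LesionMask], atlas: ConnectivityAtlas
) -> DisconnectionMatrix:
    """Masked-sum scores for every lesion x every atlas map, vectorized.

    Equivalent to calling :func:`disconnection_score` per cell; implemented
    as a (subjects x voxels) @ (voxels x ROIs) product.
    """
    ids = [l.subject_id for l in lesions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids among lesions")
    if not lesions:
        raise ValueError("no lesions supplied")
    check_same_grid(lesions[0].mask, atlas.maps[0])
    check_same_grid(*[l.mask for l in lesions])

    map_mat = atlas.stacked().T  # (n_vox, n_maps)
    n_vox = map_mat.shape[0]
    scores = np.empty((len(lesions), map_mat.shape[1]))
    for i, les in enumerate(lesions):
        idx = les.indices
        scores[i] = map_mat[idx].sum(axis=0)
    columns = atlas.roi_ids if atlas.kind != "edge_density" else [0]
    vox_vol = lesions[0].mask.voxel_volume_mm3
    volumes = pd.Series(
        {l.subject_id: l.n_voxels * vox_vol for l in lesions}, name="lesion_volume_mm3"
    )
    df = pd.DataFrame(scores, index=pd.Index(ids, name="subject_id"), columns=columns)
    return DisconnectionMatrix(
        scores=df,
        kind=atlas.kind,
        lesion_volumes_mm3=volumes,
        provenance={"atlas_kind": atlas.kind, "grid_id": atlas.grid_id, "n_voxels": n_vox},
    )


def lesion_volume(lesion: LesionMask) -> float:
    """Lesion volume in mm^3 (voxel count x voxel volume)."""
    return lesion.n_voxels * lesion.mask.voxel_volume_mm3
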