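"""Per-ROI connectivity volumes.

An atlas is a collection of one brain-wide map per cortical ROI:

* AC (anatomical connectivity): nonnegative streamline-density maps from
  tractography seeded at the ROI.
* FC (functional connectivity): signed Fisher-z correlation maps between the
  ROI's mean resting-state signal and every voxel.
* edge_density: a single map of overall grey-matter-connecting streamline
  density, used as a non-specific baseline.

This module also builds FC maps from 4D time series (band-pass filter,
nuisance regression, residual correlation, Fisher z) and combines a set of
AC maps into one network-level map via the first principal component of the
voxel-wise map stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import (
    GridMismatchError,
    Volume3D,
    check_same_grid,
    read_volume,
    write_volume,
)

__all__ = [
    "ConnectivityAtlas",
    "TimeSeries4D",
    "FCMap",
    "fisher_z",
    "build_fc_map",
    "group_average_fc",
    "build_network_ac_map",
]

# correlations of +/-1 (degenerate, e.g. a voxel inside the seed ROI) are
# capped before atanh so FC maps stay finite
R_CAP = 1.0 - 1e-12

ATLAS_KINDS = ("AC", "FC", "edge_density")


@dataclass
class ConnectivityAtlas:
    """One connectivity map per ROI (or a single edge-density map)."""

    kind: str
    maps: list[Volume3D]
    roi_ids: list[int]

    def __post_init__(self) -> None:
        if self.kind not in ATLAS_KINDS:
            raise ValueError(f"kind must be one of {ATLAS_KINDS}")
        if self.kind == "edge_density":
            if len(self.maps) != 1:
                raise ValueError("edge_density atlas holds exactly one map")
        elif len(self.maps) != len(self.roi_ids):
            raise ValueError("one map per roi_id required")
        if len(self.maps) == 0:
            raise ValueError("empty atlas")
        check_same_grid(*self.maps)
        if self.kind == "AC":
            for rid, m in zip(self.roi_ids or [0], self.maps):
                if np.any(m.data < 0):
                    raise ValueError(f"AC map for ROI {rid} has negative values")

    @property
    def grid_id(self) -> str:
        return self.maps[0].grid_id

    def map_for(self, roi_id: int) -> Volume3D:
        return self.maps[self.roi_ids.index(roi_id)]

    def subset(self, roi_ids: list[int]) -> "ConnectivityAtlas":
        return ConnectivityAtlas(
            kind=self.kind,
            maps=[self.map_for(r) for r in roi_ids],
            roi_ids=list(roi_ids),
        )

    def stacked(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_maps, n_voxels) value matrix, optionally brain-masked."""
        flat = np.stack([m.data.ravel() for m in self.maps])
        if mask is not None:
            flat = flat[:, np.asarray(mask).ravel() > 0]
        return flat

    def save(self, directory) -> None:
        """One NIfTI per ROI plus a JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        files = []
        for i, m in enumerate(self.maps):
            rid = self.roi_ids[i] if self.kind != "edge_density" else 0
            fname = f"roi_{rid:04d}.nii.gz" if self.kind != "edge_density" else "edge_density.nii.gz"
            write_volume(m, d / fname)
            files.append(fname)
        manifest = {"kind": self.kind, "roi_ids": self.roi_ids, "files": files}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "ConnectivityAtlas":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        maps = [read_volume(d / f) for f in manifest["files"]]
        return cls(kind=manifest["kind"], maps=maps, roi_ids=list(manifest["roi_ids"]))


@dataclass
class TimeSeries4D:
    """Voxel time series on the template grid."""

    data: np.ndarray  # (x, y, z, T)
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("time series must be 4D (x, y, z, T)")
        if self.data.shape[-1] < 8:
            raise ValueError("need at least 8 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s


@dataclass
class FCMap:
    """FC z-map plus QC information about undefined voxels.

    Zero-variance voxels cannot yield a correlation; their z is stored as 0
    and flagged in ``missing`` so downstream masked sums treat them as
    contributing nothing while the count remains auditable.
    """

    zmap: Volume3D
    missing: np.ndarray  # boolean, same shape

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transform z = atanh(r); requires |r| < 1."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def _bandpass(x: np.ndarray, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Ideal FFT band-pass along the last axis, after linear detrend."""
    t = x.shape[-1]
    # linear detrend
    time = np.arange(t, dtype=np.float64)
    time = (time - time.mean()) / time.std()
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x * time).mean(axis=-1, keepdims=True) / (time * time).mean()
    x = x - mean - slope * time
    freqs = np.fft.rfftfreq(t, d=tr_s)
    spec = np.fft.rfft(x, axis=-1)
    keep = (freqs > band_hz[0]) & (freqs < band_hz[1])
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def _regress_out(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize rows of x (n_series, T) against design (T, p)."""
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def build_fc_map(
    ts: TimeSeries4D,
    roi_mask: Volume3D,
    nuisance: np.ndarray | None = None,
    band_hz: tuple[float, float] = (0.009, 0.08),
) -> FCMap:
    """Seed-based FC z-map from a 4D time series.

    Recipe: linear detrend + ideal FFT band-pass within ``band_hz``,
    regression of caller-supplied nuisance columns (an intercept is added;
    callers are expected to include first temporal derivatives of their
    regressors themselves), then Pearson correlation of each voxel's
    residual with the ROI-mean residual and a Fisher z transform.  The seed
    ROI's own voxels are included.  |r| = 1 is capped just below 1.
    """
    if not (0 < band_hz[0] < band_hz[1] < ts.nyquist_hz):
        raise ValueError(
            f"band {band_hz} outside (0, Nyquist={ts.nyquist_hz:.4g} Hz)"
        )
    shape = ts.data.shape[:3]
    if tuple(roi_mask.shape) != tuple(shape):
        raise GridMismatchError("ROI mask does not match time-series grid")
    t = ts.n_timepoints
    x = ts.data.reshape(-1, t)
    x = _bandpass(x, ts.tr_s, band_hz)
    design_cols = [np.ones(t)]
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=np.float64)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != t:
            raise ValueError("nuisance matrix rows must equal time points")
        # filter the regressors identically so the projection is consistent
        design_cols.extend(_bandpass(nuis.T, ts.tr_s, band_hz))
    design = np.column_stack(design_cols)
    x = _regress_out(x, design)

    roi_idx = np.flatnonzero(roi_mask.data.ravel() > 0)
    if roi_idx.size == 0:
        raise ValueError("ROI mask is empty")
    seed = x[roi_idx].mean(axis=0)
    seed_sd = seed.std()
    if seed_sd == 0:
        raise ValueError("seed signal has zero variance after preprocessing")
    vox_sd = x.std(axis=-1)
    missing = vox_sd == 0
    vox_sd_safe = np.where(missing, 1.0, vox_sd)
    r = ((x - x.mean(-1, keepdims=True)) @ (seed - seed.mean())) / (
        t * vox_sd_safe * seed_sd
    )
    r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    z[missing] = 0.0
    return FCMap(
        zmap=Volume3D(z.reshape(shape), affine=ts.affine.copy()),
        missing=missing.reshape(shape),
    )


def group_average_fc(maps: list[FCMap | Volume3D]) -> Volume3D:
    """Voxel-wise mean z across subjects, ignoring missing voxels."""
    if not maps:
        raise ValueError("group_average_fc needs at least one map")
    vols = [m.zmap if isinstance(m, FCMap) else m for m in maps]
    check_same_grid(*vols)
    stack = np.stack([v.data for v in vols])
    valid = np.stack(
        [
            ~m.missing if isinstance(m, FCMap) else np.ones(m.shape, dtype=bool)
            for m in maps
        ]
    )
    count = valid.sum(axis=0)
    total = (stack * valid).sum(axis=0)
    out = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return vols[0].with_data(out)


def build_network_ac_map(
    atlas: ConnectivityAtlas,
    roi_subset: list[int],
    brain_mask: Volume3D,
    loading_threshold: float | None = None,
) -> Volume3D:
    """Combine a network's AC maps into one map via PCA.

    The subset maps are stacked as observations over brain-mask voxels and
    each map is centered over voxels; the first principal component's voxel
    loadings (the leading right-singular vector of the centered stack) are
    returned as a volume (zeros outside the mask), capturing the common
    regions of WM connectivity shared by the network.  The loading vector
    is oriented so its mean is nonnegative; an optional threshold zeroes
    loadings below it (the network map is sometimes used as a binary-like
    mask downstream).
    """
    if atlas.kind != "AC":
        raise ValueError("network map construction expects an AC atlas")
    if len(roi_subset) < 2:
        raise ValueError("need at least 2 ROIs to combine")
    sub = atlas.subset(list(roi_subset))
    check_same_grid(sub.maps[0], brain_mask)
    mask = brain_mask.data > 0
    m = sub.stacked(mask)  # (n_rois, n_vox)
    m = m - m.mean(axis=1, keepdims=True)
    if not np.any(m):
        raise ValueError("all-zero map stack: PCA undefined")
    # first right-singular vector = PC1 voxel loadings
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    loadings = vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
    if loading_threshold is not None:
        loadings = np.where(loadings >= loading_threshold, loadings, 0.0)
    out = np.zeros(brain_mask.shape)
    out[mask] = loadings
    return brain_mask.with_data(out)
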