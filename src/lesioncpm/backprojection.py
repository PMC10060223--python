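"""Back-projection of ROI-level predictiveness onto white-matter voxels.

Given the per-ROI t-scores from CPM feature selection and each ROI's
brain-wide AC map, a per-voxel simple regression across ROIs (t-score on
the ROI's streamline value at that voxel, with intercept) identifies voxels
whose connectivity profile tracks ROI predictiveness: high slope-t voxels
carry streamlines predominantly to ROIs whose disconnection predicts
impaired cognitive control.

Family-wise error is controlled by permuting the assignment of t-scores to
ROIs (exchangeable under the null that connectivity profiles carry no
information about ROI predictiveness) and recording the map-wise maximum of
|t| — optionally TFCE-enhanced — per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .connectivity_maps import ConnectivityAtlas
from .volumes import Volume3D

__all__ = [
    "BackprojectionConfig",
    "StatMap",
    "voxelwise_glm",
    "tfce_transform",
    "permutation_correct",
]

T_CAP = 1e8  # slope t reported for numerically perfect fits

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class BackprojectionConfig:
    n_perm: int = 2000
    correction: str = "tfce"  # "max_stat" or "tfce"
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = 100
    connectivity: int = 26
    two_tailed: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.correction not in ("max_stat", "tfce"):
            raise ValueError("correction must be 'max_stat' or 'tfce'")
        if self.tfce_E <= 0 or self.tfce_H <= 0:
            raise ValueError("TFCE E and H must be positive")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class StatMap:
    t_map: Volume3D
    p_corr_map: Volume3D
    mask: Volume3D  # binary: p_corr < alpha
    config: BackprojectionConfig = field(default_factory=BackprojectionConfig)
    seed: int | None = None


def _slope_t(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Slope t-statistics for simple regressions with intercept.

    A: (n_roi, n_vox) predictor values per voxel; Y: (B, n_roi) outcome
    vectors.  Returns (B, n_vox).  Zero-variance voxels get t = 0;
    numerically perfect fits are capped at +/- T_CAP.
    """
    n = A.shape[0]
    Ac = A - A.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (Ac**2).sum(axis=0)  # (n_vox,)
    syy = (Yc**2).sum(axis=1, keepdims=True)  # (B, 1)
    sxy = Yc @ Ac  # (B, n_vox)
    denom2 = sxx[None, :] * syy - sxy**2
    zero_var = (sxx == 0)[None, :] | (syy == 0)
    perfect = (denom2 <= 0) & ~zero_var
    with np.errstate(divide="ignore", invalid="ignore"):
        t = sxy * np.sqrt((n - 2) / np.where(denom2 <= 0, 1.0, denom2))
    t = np.where(perfect, np.sign(sxy) * T_CAP, t)
    t = np.where(zero_var, 0.0, t)
    return t


def voxelwise_glm(
    atlas: ConnectivityAtlas,
    t_scores: np.ndarray,
    brain_mask: Volume3D | None = None,
) -> Volume3D:
    """Per-voxel slope t of ROI t-scores regressed on AC values across ROIs."""
    y = np.asarray(t_scores, dtype=np.float64)
    if y.size != len(atlas.maps):
        raise ValueError("t_scores length must match the number of atlas ROIs")
    if y.size < 4:
        raise ValueError("need at least 4 ROIs")
    template = atlas.maps[0]
    mask = None if brain_mask is None else (brain_mask.data > 0)
    A = atlas.stacked(mask)
    t = _slope_t(A, y[None, :])[0]
    out = np.zeros(template.shape)
    if mask is None:
        out = t.reshape(template.shape)
    else:
        out[mask] = t
    return template.with_data(out)


def tfce_transform(
    stat: Volume3D | np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh_steps: int = 100,
    connectivity: int = 26,
) -> Volume3D | np.ndarray:
    """Threshold-free cluster enhancement of a nonnegative statistic map.

    TFCE(v) = sum over thresholds h of e(h, v)^E * h^H * dh, where e(h, v)
    is the size of the suprathreshold cluster containing v at height h and
    dh = max(stat)/dh_steps.  Negative input is an error: two-tailed users
    enhance the positive and negative branches separately.
    """
    data = stat.data if isinstance(stat, Volume3D) else np.asarray(stat, dtype=np.float64)
    if np.any(data < 0):
        raise ValueError(
            "TFCE input must be nonnegative; split |t| into positive and "
            "negative branches for two-tailed use"
        )
    if dh_steps < 10:
        raise ValueError("dh_steps must be >= 10")
    out = np.zeros_like(data)
    hmax = data.max()
    if hmax > 0:
        dh = hmax / dh_steps
        struct = _STRUCTS[connectivity]
        for i in range(1, dh_steps + 1):
            h = i * dh
            supra = data >= h
            if not supra.any():
                break
            labels, n = ndimage.label(supra, structure=struct)
            sizes = np.bincount(labels.ravel())
            out[supra] += (sizes[labels[supra]] ** E) * (h**H) * dh
    if isinstance(stat, Volume3D):
        return stat.with_data(out)
    return out


def _enhanced_stat(
    t_flat: np.ndarray,
    shape: tuple[int, int, int],
    mask: np.ndarray | None,
    config: BackprojectionConfig,
) -> np.ndarray:
    """Two-tailed voxel statistic: |t|, optionally TFCE per sign branch."""
    full = np.zeros(shape)
    if mask is None:
        full = t_flat.reshape(shape)
    else:
        full[mask] = t_flat
    if not config.two_tailed:
        full = np.clip(full, 0.0, None)
    if config.correction == "max_stat":
        stat = np.abs(full) if config.two_tailed else full
    else:
        pos = tfce_transform(
            np.clip(full, 0.0, None), config.tfce_E, config.tfce_H,
            config.tfce_steps, config.connectivity,
        )
        if config.two_tailed:
            neg = tfce_transform(
                np.clip(-full, 0.0, None), config.tfce_E, config.tfce_H,
                config.tfce_steps, config.connectivity,
            )
            stat = np.maximum(pos, neg)
        else:
            stat = pos
    if mask is not None:
        return stat[mask]
    return stat.ravel()


def permutation_correct(
    atlas: ConnectivityAtlas,
    t_scores: np.ndarray,
    config: BackprojectionConfig | None = None,
    seed: int | None = None,
    brain_mask: Volume3D | None = None,
) -> StatMap:
    """Permutation-corrected voxel map of the back-projection GLM.

    The null permutes t_scores across ROIs; each permutation's map-wise
    maximum statistic forms the null, and the corrected p per voxel is
    (1 + #{null max >= observed}) / (1 + n_perm).
    """
    config = config or BackprojectionConfig()
    y = np.asarray(t_scores, dtype=np.float64)
    if y.size != len(atlas.maps):
        raise ValueError("t_scores length must match the number of atlas ROIs")
    if 1.0 / (config.n_perm + 1) > config.alpha:
        import warnings

        warnings.warn(
            f"n_perm={config.n_perm} cannot reach alpha={config.alpha}",
            stacklevel=2,
        )
    template = atlas.maps[0]
    shape = template.shape
    mask = None if brain_mask is None else (brain_mask.data > 0)
    A = atlas.stacked(mask)

    t_obs_flat = _slope_t(A, y[None, :])[0]
    obs_stat = _enhanced_stat(t_obs_flat, shape, mask, config)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(config.n_perm)])
    null_max = np.empty(config.n_perm)
    if config.correction == "max_stat":
        # vectorize in chunks: only the map-wise max is needed
        chunk = max(1, int(2e7 // max(A.shape[1], 1)))
        for start in range(0, config.n_perm, chunk):
            tt = _slope_t(A, perms[start : start + chunk])
            null_max[start : start + chunk] = np.abs(tt).max(axis=1)
    else:
        for b in range(config.n_perm):
            t_b = _slope_t(A, perms[b : b + 1])[0]
            null_max[b] = _enhanced_stat(t_b, shape, mask, config).max()

    exceed = (null_max[None, :] >= obs_stat[:, None]).sum(axis=1)
    p_flat = (1 + exceed) / (1 + config.n_perm)

    def unflatten(flat: np.ndarray, fill: float) -> np.ndarray:
        if mask is None:
            return flat.reshape(shape)
        out = np.full(shape, fill)
        out[mask] = flat
        return out

    t_map = template.with_data(unflatten(t_obs_flat, 0.0))
    p_map = template.with_data(unflatten(p_flat, 1.0))
    sig = template.with_data((p_map.data < config.alpha).astype(np.float64))
    return StatMap(t_map=t_map, p_corr_map=p_map, mask=sig, config=config, seed=seed)
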