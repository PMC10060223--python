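"""Empirical null distributions for specificity claims.

Two nulls:

* cluster relocation — are significant clusters placed where they overlap a
  reference map more than chance?  Each iteration rigidly translates every
  cluster (shape preserved, independent uniform translations, rejection-
  sampled to stay fully inside the brain mask) and recomputes the overlap.
* random ROI sets — does an a priori network of k ROIs predict better than
  k ROIs drawn at random?  Each iteration reruns the full CPM train/test on
  a random subset and records the test AIC.

Empirical p-values use the add-one convention (1 + #{null at least as
extreme}) / (1 + B), so p is never exactly zero and is bounded below by
1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import ScoreVector
from .cpm import train_test_cpm
from .disconnection import DisconnectionMatrix
from .model_comparison import aic
from .volumes import ClusterSet, Volume3D, check_same_grid

__all__ = ["PermutationResult", "cluster_overlap_null", "random_roi_null"]


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p: float
    B: int
    seed: int | None
    alternative: str = "greater"
    degenerate: bool = False
    extra: dict | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p": self.p,
            "B": self.B,
            "seed": self.seed,
            "alternative": self.alternative,
            "degenerate": self.degenerate,
            "null_values": list(map(float, self.null_values)),
        }


def _empirical_p(observed: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    elif alternative == "less":
        extreme = int(np.sum(null <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (1 + extreme) / (1 + null.size)


def _relocate_cluster(
    coords: np.ndarray,
    inside: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 2000,
) -> np.ndarray:
    """Random rigid translation of a voxel set, fully inside the mask."""
    shape = np.asarray(inside.shape)
    base = coords - coords.min(axis=0)
    extent = base.max(axis=0)
    hi = shape - extent  # exclusive upper bound on the min-corner offset
    if np.any(hi <= 0):
        raise ValueError("cluster larger than the brain mask extent")
    for _ in range(max_attempts):
        offset = rng.integers(0, hi)
        cand = base + offset
        if inside[cand[:, 0], cand[:, 1], cand[:, 2]].all():
            return cand
    raise RuntimeError(
        f"could not place a cluster of {len(coords)} voxels inside the mask "
        f"after {max_attempts} attempts"
    )


def cluster_overlap_null(
    clusters_a: ClusterSet,
    map_b: Volume3D,
    brain_mask: Volume3D,
    B: int = 1000,
    mode: str = "count_overlap",
    seed: int | None = None,
    threshold: float = 0.0,
) -> PermutationResult:
    """Null distribution of cluster/map overlap under random relocation.

    ``mode``: "count_overlap" counts voxels of the relocated clusters where
    map_b > threshold; "weighted_overlap" sums map_b values under them.
    Relocated clusters may overlap each other; overlapping voxels are
    counted once (the union of voxel sets is scored).
    """
    if B < 19:
        raise ValueError("B must be >= 19 for a meaningful empirical p")
    if mode not in ("count_overlap", "weighted_overlap"):
        raise ValueError("mode must be 'count_overlap' or 'weighted_overlap'")
    check_same_grid(map_b, brain_mask)
    if not clusters_a.clusters:
        raise ValueError("empty cluster set")
    inside = brain_mask.data > 0
    shape = inside.shape

    def score(cluster_coords: list[np.ndarray]) -> float:
        union = np.zeros(shape, dtype=bool)
        for c in cluster_coords:
            union[c[:, 0], c[:, 1], c[:, 2]] = True
        if mode == "count_overlap":
            return float(np.count_nonzero(union & (map_b.data > threshold)))
        return float(map_b.data[union].sum())

    observed = score(clusters_a.clusters)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = score(
            [_relocate_cluster(c, inside, rng) for c in clusters_a.clusters]
        )
    p = _empirical_p(observed, null, "greater")
    degenerate = bool(np.all(null == null[0]) and null[0] == observed)
    return PermutationResult(
        observed=observed, null_values=null, p=p, B=B, seed=seed,
        alternative="greater", degenerate=degenerate,
        extra={"mode": mode},
    )


def random_roi_null(
    X_train: DisconnectionMatrix | pd.DataFrame,
    X_test: DisconnectionMatrix | pd.DataFrame,
    y_train: ScoreVector | np.ndarray,
    y_test: ScoreVector | np.ndarray,
    k: int,
    B: int = 1000,
    seed: int | None = None,
    observed_roi_ids: list[int] | None = None,
    alpha: float = 0.01,
    sign_policy: str = "positive_only",
    aic_k: int = 1,
) -> PermutationResult:
    """Test-AIC null over random k-ROI subsets (lower AIC is better).

    The observed statistic is the test AIC of the CPM restricted to
    ``observed_roi_ids`` (e.g. the a priori network).  Iterations sample k
    ROIs without replacement from the full atlas and rerun the identical
    train/test pipeline; degenerate (zero-feature) iterations fall back to
    training-mean prediction rather than being skipped, so the null is not
    biased toward informative subsets.
    """
    df_train = X_train.scores if isinstance(X_train, DisconnectionMatrix) else X_train
    df_test = X_test.scores if isinstance(X_test, DisconnectionMatrix) else X_test
    all_rois = list(df_train.columns)
    if k > len(all_rois):
        raise ValueError("k exceeds the number of ROIs")
    if observed_roi_ids is None:
        raise ValueError("observed_roi_ids (the a priori ROI set) is required")
    if len(observed_roi_ids) != k:
        raise ValueError("observed ROI set must have size k")

    def test_aic(roi_ids: list[int]) -> tuple[float, bool]:
        pred = train_test_cpm(
            df_train[roi_ids], y_train, df_test[roi_ids], y_test,
            alpha=alpha, sign_policy=sign_policy,
        )
        return aic(pred, k=aic_k), bool(pred.provenance.get("degenerate"))

    observed, _ = test_aic(list(observed_roi_ids))
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    n_degenerate = 0
    roi_arr = np.asarray(all_rois)
    for b in range(B):
        subset = list(roi_arr[rng.choice(len(roi_arr), size=k, replace=False)])
        null[b], deg = test_aic(subset)
        n_degenerate += int(deg)
    p = _empirical_p(observed, null, "less")
    return PermutationResult(
        observed=observed, null_values=null, p=p, B=B, seed=seed,
        alternative="less",
        extra={"k": k, "n_degenerate_iterations": n_degenerate},
    )
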