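"""Lesion-adapted connectome-based predictive modeling (CPM).

Feature selection: each ROI's disconnection scores are correlated with the
behavioral score across training subjects; a ROI enters the model when its
two-sided Pearson p-value is below ``alpha`` (default 0.01) and satisfies
the sign policy — ``positive_only`` for AC and edge-density scores (more
disconnection must predict worse performance), ``two_sided`` for FC.

Prediction: one univariate OLS regression of behavior on each selected
ROI's score; the prediction for a new subject is the equal-weight average
of the per-ROI predictions.  A model with no selected ROI is degenerate and
predicts the training mean, so downstream AIC comparisons stay computable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import ScoreVector
from .disconnection import DisconnectionMatrix

__all__ = [
    "FeatureSelectionResult",
    "CPMModel",
    "PredictionRecord",
    "select_features",
    "fit_cpm",
    "predict_cpm",
    "crossval_cpm",
    "roi_tscores",
]

SIGN_POLICIES = ("positive_only", "two_sided")


def _as_xy(
    X: DisconnectionMatrix | pd.DataFrame, y: ScoreVector | np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    df = X.scores if isinstance(X, DisconnectionMatrix) else X
    if isinstance(y, ScoreVector):
        if list(df.index) != list(y.subject_ids):
            raise ValueError("X rows and y subjects are not aligned")
        yv = y.values
    else:
        yv = np.asarray(y, dtype=np.float64)
        if yv.size != len(df):
            raise ValueError("X rows and y length mismatch")
    if np.any(np.isnan(yv)):
        keep = ~np.isnan(yv)
        df = df.loc[keep]
        yv = yv[keep]
    return df, yv


@dataclass
class FeatureSelectionResult:
    roi_ids: list[int]
    r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    selected: np.ndarray  # boolean
    alpha: float
    sign_policy: str
    n: int

    @property
    def selected_roi_ids(self) -> list[int]:
        return [rid for rid, s in zip(self.roi_ids, self.selected) if s]


@dataclass
class CPMModel:
    roi_ids: list[int]  # selected ROIs
    intercepts: np.ndarray
    slopes: np.ndarray
    training_n: int
    fallback_mean: float
    alpha: float
    sign_policy: str
    degenerate: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "roi_ids": [int(r) for r in self.roi_ids],
                    "intercepts": list(map(float, self.intercepts)),
                    "slopes": list(map(float, self.slopes)),
                    "training_n": self.training_n,
                    "fallback_mean": self.fallback_mean,
                    "alpha": self.alpha,
                    "sign_policy": self.sign_policy,
                    "degenerate": self.degenerate,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CPMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            roi_ids=list(d["roi_ids"]),
            intercepts=np.asarray(d["intercepts"]),
            slopes=np.asarray(d["slopes"]),
            training_n=d["training_n"],
            fallback_mean=d["fallback_mean"],
            alpha=d["alpha"],
            sign_policy=d["sign_policy"],
            degenerate=d["degenerate"],
        )


@dataclass
class PredictionRecord:
    subject_ids: list[str]
    y: np.ndarray
    y_hat: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64)
        if not (len(self.subject_ids) == self.y.size == self.y_hat.size):
            raise ValueError("subject_ids, y, y_hat length mismatch")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.y_hat))):
            raise ValueError("predictions must be finite")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.y_hat

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"subject_id": self.subject_ids, "y": self.y, "y_hat": self.y_hat}
        ).to_csv(path, sep="\t", index=False)


def _pearson_stats(Xv: np.ndarray, yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r, t (n-2 df) and two-sided p.

    Constant columns get r = t = 0, p = 1.
    """
    n = yv.size
    xc = Xv - Xv.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = (sx == 0) | (sy == 0)
    denom = np.where(constant, 1.0, sx * sy)
    r = (xc.T @ yc) / denom
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[constant] = 1.0
    return r, t, p


def select_features(
    X: DisconnectionMatrix | pd.DataFrame,
    y: ScoreVector | np.ndarray,
    alpha: float = 0.01,
    sign_policy: str = "positive_only",
) -> FeatureSelectionResult:
    """Per-ROI Pearson screening at uncorrected two-sided p < alpha."""
    if sign_policy not in SIGN_POLICIES:
        raise ValueError(f"sign_policy must be one of {SIGN_POLICIES}")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    df, yv = _as_xy(X, y)
    n = yv.size
    if n < 4:
        raise ValueError(f"need n >= 4 training subjects, got {n}")
    r, t, p = _pearson_stats(df.to_numpy(dtype=np.float64), yv)
    selected = p < alpha
    if sign_policy == "positive_only":
        selected &= r > 0
    return FeatureSelectionResult(
        roi_ids=list(df.columns),
        r=r,
        t=t,
        p=p,
        selected=selected,
        alpha=alpha,
        sign_policy=sign_policy,
        n=n,
    )


def fit_cpm(
    X: DisconnectionMatrix | pd.DataFrame,
    y: ScoreVector | np.ndarray,
    selection: FeatureSelectionResult,
) -> CPMModel:
    """Per-ROI univariate OLS of behavior on disconnection score."""
    df, yv = _as_xy(X, y)
    sel_ids = selection.selected_roi_ids
    if not sel_ids:
        return CPMModel(
            roi_ids=[],
            intercepts=np.empty(0),
            slopes=np.empty(0),
            training_n=yv.size,
            fallback_mean=float(yv.mean()),
            alpha=selection.alpha,
            sign_policy=selection.sign_policy,
            degenerate=True,
        )
    xs = df[sel_ids].to_numpy(dtype=np.float64)
    xc = xs - xs.mean(axis=0)
    var = (xc**2).sum(axis=0)
    if np.any(var == 0):
        raise RuntimeError("zero-variance ROI passed feature selection")
    slopes = (xc.T @ (yv - yv.mean())) / var
    intercepts = yv.mean() - slopes * xs.mean(axis=0)
    return CPMModel(
        roi_ids=list(sel_ids),
        intercepts=intercepts,
        slopes=slopes,
        training_n=yv.size,
        fallback_mean=float(yv.mean()),
        alpha=selection.alpha,
        sign_policy=selection.sign_policy,
    )


def predict_cpm(
    model: CPMModel, X_test: DisconnectionMatrix | pd.DataFrame,
    y_test: ScoreVector | np.ndarray | None = None,
) -> PredictionRecord:
    """Average of per-ROI univariate predictions for each test subject."""
    df = X_test.scores if isinstance(X_test, DisconnectionMatrix) else X_test
    if y_test is not None:
        df, yv = _as_xy(X_test, y_test)
    else:
        yv = np.full(len(df), np.nan)
    if model.degenerate:
        y_hat = np.full(len(df), model.fallback_mean)
    else:
        missing = [r for r in model.roi_ids if r not in df.columns]
        if missing:
            raise ValueError(f"test matrix lacks selected ROIs: {missing}")
        xs = df[model.roi_ids].to_numpy(dtype=np.float64)
        per_roi = model.intercepts + model.slopes * xs
        y_hat = per_roi.mean(axis=1)
    if y_test is None:
        yv = y_hat  # placeholder so the record stays finite
    return PredictionRecord(
        subject_ids=list(df.index),
        y=yv,
        y_hat=y_hat,
        provenance={
            "n_features": len(model.roi_ids),
            "degenerate": model.degenerate,
            "training_n": model.training_n,
        },
    )


def train_test_cpm(
    X_train, y_train, X_test, y_test,
    alpha: float = 0.01, sign_policy: str = "positive_only",
) -> PredictionRecord:
    """Convenience: select on train, fit on train, predict held-out test."""
    sel = select_features(X_train, y_train, alpha=alpha, sign_policy=sign_policy)
    model = fit_cpm(X_train, y_train, sel)
    return predict_cpm(model, X_test, y_test)


def crossval_cpm(
    X: DisconnectionMatrix | pd.DataFrame,
    y: ScoreVector | np.ndarray,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    alpha: float = 0.01,
    sign_policy: str = "positive_only",
) -> PredictionRecord:
    """Out-of-fold CPM predictions with selection nested inside each fold.

    ``scheme``: "loo" (deterministic, the default) or "kfold" (requires
    ``seed`` for the shuffle).  Pooled out-of-fold predictions are returned
    in the original subject order.
    """
    df, yv = _as_xy(X, y)
    n = yv.size
    if scheme not in ("loo", "kfold"):
        raise ValueError("scheme must be 'loo' or 'kfold'")
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds n={n}")
        if n < 10:
            raise ValueError("k-fold cross-validation needs n >= 10")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = [np.sort(f) for f in np.array_split(order, k)]
    y_hat = np.empty(n)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if train_mask.sum() < 4:
            raise ValueError("a training fold has fewer than 4 subjects")
        Xtr, Xte = df.iloc[train_mask], df.iloc[test_idx]
        sel = select_features(Xtr, yv[train_mask], alpha=alpha, sign_policy=sign_policy)
        model = fit_cpm(Xtr, yv[train_mask], sel)
        y_hat[test_idx] = predict_cpm(model, Xte).y_hat
    return PredictionRecord(
        subject_ids=list(df.index),
        y=yv,
        y_hat=y_hat,
        provenance={"cv": scheme, "k": k if scheme == "kfold" else n, "seed": seed},
    )


def roi_tscores(
    X: DisconnectionMatrix | pd.DataFrame, y: ScoreVector | np.ndarray
) -> pd.Series:
    """Selection-stage t statistic for every ROI (selected or not).

    This is the vector back-projected onto white matter voxels.
    """
    sel = select_features(X, y, alpha=0.5, sign_policy="two_sided")
    return pd.Series(sel.t, index=sel.roi_ids, name="t")
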