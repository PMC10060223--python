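"""Prediction-performance comparison between models.

Prediction quality of a model evaluated on held-out subjects is summarized
by the Akaike information criterion on the Gaussian residual likelihood,

    AIC = n * ln(RSS / n) + 2k,      RSS = sum((y - y_hat)^2),

with k = 1 by default (the residual variance is the only estimated
quantity entering the criterion, and k is held identical across compared
models, so differences reduce to n*ln(RSS1/RSS2)).  Two models M1, M2 are
compared with the evidence-ratio rule

    L = exp((AIC1 - AIC2) / 2),      p = L / (1 + L),

a one-sided test of the null that M1 does not outperform M2 (callers put
the hypothesized better model first; negative dAIC favors M1).  Effect size
is the ratio R >= 1 of root-mean-square prediction errors, worse model over
better.  For models with equal k evaluated on the same subjects,
dAIC = 2 n ln(R) exactly.  Confidence intervals come from a percentile
bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cpm import PredictionRecord

__all__ = [
    "ModelComparison",
    "aic",
    "aic_pvalue",
    "prediction_error_ratio",
    "sigma_e",
    "bootstrap_ci",
    "fdr_bh",
    "compare_models",
]


def aic(pred: PredictionRecord, k: int = 1) -> float:
    """Gaussian-residual AIC of a prediction record."""
    n = pred.n
    if n < 2:
        raise ValueError("AIC needs at least 2 subjects")
    rss = float((pred.residuals**2).sum())
    if rss == 0:
        raise ValueError(
            "perfect prediction (RSS = 0): AIC undefined; jitter or flag upstream"
        )
    return n * np.log(rss / n) + 2 * k


def aic_pvalue(aic_1: float, aic_2: float) -> tuple[float, float]:
    """Evidence ratio L and one-sided p for 'M1 outperforms M2'.

    Extreme negative dAIC underflows L toward 0 and p toward 0; extreme
    positive dAIC overflows L to inf with p computed stably via the
    logistic form p = 1 / (1 + exp(-dAIC/2)).
    """
    if not (np.isfinite(aic_1) and np.isfinite(aic_2)):
        raise ValueError("AIC inputs must be finite")
    half = (aic_1 - aic_2) / 2.0
    with np.errstate(over="ignore"):
        L = float(np.exp(half))
    from scipy.special import expit

    p = float(expit(half))
    return L, p


def sigma_e(pred: PredictionRecord) -> float:
    """Root-mean-square prediction error sqrt(RSS/n)."""
    return float(np.sqrt((pred.residuals**2).mean()))


def prediction_error_ratio(pred_1: PredictionRecord, pred_2: PredictionRecord) -> float:
    """Effect size R: ratio of rms prediction errors, worse over better."""
    if pred_1.n != pred_2.n:
        raise ValueError("prediction records must cover the same subjects")
    s1, s2 = sigma_e(pred_1), sigma_e(pred_2)
    lo = min(s1, s2)
    if lo == 0:
        raise ValueError("zero prediction error: ratio undefined")
    return max(s1, s2) / lo


def _resample(pred: PredictionRecord, idx: np.ndarray) -> PredictionRecord:
    return PredictionRecord(
        subject_ids=[pred.subject_ids[i] for i in idx],
        y=pred.y[idx],
        y_hat=pred.y_hat[idx],
    )


def bootstrap_ci(
    pred: PredictionRecord,
    statistic: Callable[[PredictionRecord], float] | str = "sigma_e",
    B: int = 100,
    level: float = 95.0,
    seed: int | None = None,
    k: int = 1,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subjects, resampled with replacement.

    ``statistic`` is "sigma_e", "aic", or any callable on a
    PredictionRecord.  Resamples on which the statistic is undefined (e.g.
    RSS = 0 for AIC) are redrawn, up to ``max_redraws`` extra draws total.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if pred.n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    n = pred.n
    if statistic in ("sigma_e", "aic"):
        # fast path: both depend on residuals only
        res2 = pred.residuals**2
        idx = rng.integers(0, n, size=(B, n))
        rss = res2[idx].sum(axis=1)
        # RSS = 0 leaves sigma_e defined (zero) but AIC undefined
        bad = np.flatnonzero(rss == 0) if statistic == "aic" else np.empty(0, int)
        redraws = 0
        while bad.size:
            redraws += bad.size
            if redraws > max_redraws:
                raise ValueError("statistic undefined on too many bootstrap resamples")
            rss[bad] = res2[rng.integers(0, n, size=(bad.size, n))].sum(axis=1)
            bad = bad[rss[bad] == 0]
        if statistic == "sigma_e":
            vals = np.sqrt(rss / n)
        else:
            vals = n * np.log(rss / n) + 2 * k
    elif callable(statistic):
        stat = statistic
        vals = np.empty(B)
        redraws = 0
        for b in range(B):
            while True:
                idx = rng.integers(0, n, size=n)
                try:
                    vals[b] = stat(_resample(pred, idx))
                    break
                except ValueError:
                    redraws += 1
                    if redraws > max_redraws:
                        raise ValueError(
                            "statistic undefined on too many bootstrap resamples"
                        )
    else:
        raise ValueError("statistic must be 'sigma_e', 'aic' or a callable")
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(vals, [tail, 100.0 - tail])
    return float(lo), float(hi)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (reject flags, adjusted p)."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class ModelComparison:
    """Paired comparison report (M1 hypothesized better; lower AIC wins)."""

    aic_1: float
    aic_2: float
    L: float
    p: float
    R: float
    ci_1: tuple[float, float] | None = None
    ci_2: tuple[float, float] | None = None
    n: int = 0
    k: int = 1
    seed: int | None = None
    labels: tuple[str, str] = ("M1", "M2")
    extra: dict = field(default_factory=dict)

    @property
    def delta_aic(self) -> float:
        return self.aic_1 - self.aic_2

    def to_dict(self) -> dict:
        return {
            "model_1": self.labels[0],
            "model_2": self.labels[1],
            "aic_1": self.aic_1,
            "aic_2": self.aic_2,
            "delta_aic": self.delta_aic,
            "L": self.L,
            "p": self.p,
            "R": self.R,
            "ci_1": self.ci_1,
            "ci_2": self.ci_2,
            "n": self.n,
            "k": self.k,
            "seed": self.seed,
        }


def compare_models(
    pred_1: PredictionRecord,
    pred_2: PredictionRecord,
    k: int = 1,
    B_bootstrap: int = 100,
    seed: int | None = None,
    labels: tuple[str, str] = ("M1", "M2"),
) -> ModelComparison:
    """Full comparison: AICs, dAIC evidence p, effect size R, bootstrap CIs."""
    a1, a2 = aic(pred_1, k=k), aic(pred_2, k=k)
    L, p = aic_pvalue(a1, a2)
    R = prediction_error_ratio(pred_1, pred_2)
    ci_1 = bootstrap_ci(pred_1, "aic", B=B_bootstrap, seed=seed, k=k)
    ci_2 = bootstrap_ci(
        pred_2, "aic", B=B_bootstrap, seed=None if seed is None else seed + 1, k=k
    )
    return ModelComparison(
        aic_1=a1, aic_2=a2, L=L, p=p, R=R,
        ci_1=ci_1, ci_2=ci_2, n=pred_1.n, k=k, seed=seed, labels=labels,
    )
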