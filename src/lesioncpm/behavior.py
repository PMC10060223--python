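"""Cognitive-control behavioral scores.

Two neuropsychological tasks are supported:

* Trail-making test (TMT): part B time minus part A time, log-transformed.
  B-A isolates switching / working-memory demand from motor and visual
  search speed, and the log reduces the impact of slow outliers.
* Stroop colour-word task: correct counts in a fixed response window are
  converted to seconds-per-correct-response, and the interference score is
  CW - (C + W)/2 on that response-time scale, log-transformed.  It isolates
  inhibition of the habitual reading response.

Natural logarithm throughout; the base only rescales scores linearly and is
irrelevant to correlation-based modeling.  Subjects whose score is undefined
(e.g. TMT B <= A, or nonpositive interference) are flagged missing, never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralRecord",
    "ScoreVector",
    "BehaviorDomainError",
    "tmt_score",
    "stroop_interference",
    "standardize_scores",
    "read_behavior_table",
    "score_records",
]

DEFAULT_STROOP_WINDOW_S = 45.0


class BehaviorDomainError(ValueError):
    """Raised when a behavioral score is undefined for the given inputs."""


@dataclass
class BehavioralRecord:
    subject_id: str
    tmt_a_s: float | None = None
    tmt_b_s: float | None = None
    stroop_c_correct: int | None = None
    stroop_w_correct: int | None = None
    stroop_cw_correct: int | None = None
    window_s: float = DEFAULT_STROOP_WINDOW_S

    def __post_init__(self) -> None:
        for name in ("tmt_a_s", "tmt_b_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise BehaviorDomainError(f"{name} must be positive, got {v}")
        for name in ("stroop_c_correct", "stroop_w_correct", "stroop_cw_correct"):
            v = getattr(self, name)
            if v is not None:
                if v != int(v) or v < 0:
                    raise BehaviorDomainError(f"{name} must be a nonnegative integer")
                setattr(self, name, int(v))


@dataclass
class ScoreVector:
    """Per-subject behavioral scores; missing entries are NaN."""

    subject_ids: list[str]
    values: np.ndarray
    task: str  # "TMT" or "Stroop"
    transformed: bool = True
    standardized: bool = False
    reference: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.subject_ids) != self.values.size:
            raise ValueError("subject_ids and values length mismatch")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def dropna(self) -> "ScoreVector":
        keep = ~np.isnan(self.values)
        return ScoreVector(
            subject_ids=[s for s, k in zip(self.subject_ids, keep) if k],
            values=self.values[keep],
            task=self.task,
            transformed=self.transformed,
            standardized=self.standardized,
            reference=self.reference,
        )


def tmt_score(a_s: float, b_s: float) -> float:
    """ln(TMT B - TMT A), both in seconds; requires B > A > 0."""
    if a_s <= 0 or b_s <= 0:
        raise BehaviorDomainError("TMT times must be positive")
    if b_s <= a_s:
        raise BehaviorDomainError(
            f"TMT B ({b_s}s) must exceed TMT A ({a_s}s) for a defined B-A score"
        )
    return math.log(b_s - a_s)


def stroop_interference(
    c: int, w: int, cw: int, window_s: float = DEFAULT_STROOP_WINDOW_S
) -> float:
    """ln of the response-time interference score CW - (C + W)/2.

    Counts are correct responses within ``window_s`` seconds; response time
    per item is window_s / count.
    """
    for name, v in (("c", c), ("w", w), ("cw", cw)):
        if v < 1:
            raise BehaviorDomainError(f"Stroop count {name}={v}; needs >= 1 correct")
    if window_s <= 0:
        raise BehaviorDomainError("window_s must be positive")
    rt_c, rt_w, rt_cw = window_s / c, window_s / w, window_s / cw
    interference = rt_cw - (rt_c + rt_w) / 2.0
    if interference <= 0:
        raise BehaviorDomainError(
            f"nonpositive interference ({interference:.4g}); score undefined"
        )
    return math.log(interference)


def standardize_scores(
    v: ScoreVector, reference: tuple[float, float] | None = None
) -> ScoreVector:
    """z-score a ScoreVector; missing entries propagate.

    With no ``reference``, the sample mean and sample SD (ddof=1) of the
    non-missing entries are used.  A ``reference`` (mean, sd) pair applies
    external statistics instead — used when a test sample must be scored on
    a training sample's scale.
    """
    vals = v.values
    finite = vals[~np.isnan(vals)]
    if reference is None:
        if finite.size < 2:
            raise ValueError("need >= 2 non-missing values to standardize")
        mean = float(np.mean(finite))
        sd = float(np.std(finite, ddof=1))
        if sd == 0:
            raise ValueError("zero variance: cannot standardize without a reference")
    else:
        mean, sd = float(reference[0]), float(reference[1])
        if sd <= 0:
            raise ValueError("reference sd must be positive")
    return ScoreVector(
        subject_ids=list(v.subject_ids),
        values=(vals - mean) / sd,
        task=v.task,
        transformed=v.transformed,
        standardized=True,
        reference=(mean, sd),
    )


def read_behavior_table(path) -> list[BehavioralRecord]:
    """Read a CSV/TSV behavioral table (columns: subject_id, tmt_a_s,
    tmt_b_s, stroop_c, stroop_w, stroop_cw; missing values as empty cells)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: behavioral table needs a subject_id column")

    def _get(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return row[col]

    records = []
    for _, row in df.iterrows():
        records.append(
            BehavioralRecord(
                subject_id=str(row["subject_id"]),
                tmt_a_s=_get(row, "tmt_a_s"),
                tmt_b_s=_get(row, "tmt_b_s"),
                stroop_c_correct=_get(row, "stroop_c"),
                stroop_w_correct=_get(row, "stroop_w"),
                stroop_cw_correct=_get(row, "stroop_cw"),
            )
        )
    return records


def score_records(records: list[BehavioralRecord], task: str) -> ScoreVector:
    """Compute log-scores for one task; undefined/missing scores become NaN."""
    if task not in ("TMT", "Stroop"):
        raise ValueError("task must be 'TMT' or 'Stroop'")
    vals = np.full(len(records), np.nan)
    for i, rec in enumerate(records):
        try:
            if task == "TMT":
                if rec.tmt_a_s is None or rec.tmt_b_s is None:
                    continue
                vals[i] = tmt_score(rec.tmt_a_s, rec.tmt_b_s)
            else:
                if None in (
                    rec.stroop_c_correct,
                    rec.stroop_w_correct,
                    rec.stroop_cw_correct,
                ):
                    continue
                vals[i] = stroop_interference(
                    rec.stroop_c_correct,
                    rec.stroop_w_correct,
                    rec.stroop_cw_correct,
                    rec.window_s,
                )
        except BehaviorDomainError:
            vals[i] = np.nan
    return ScoreVector(
        subject_ids=[r.subject_id for r in records], values=vals, task=task
    )
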