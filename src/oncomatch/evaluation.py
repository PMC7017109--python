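"""Retrospective validation statistics.

A treatment line is *successful* when it produced a complete or partial
RECIST response, or stable disease lasting at least 12 months; every
other line is unsuccessful. Against these binary labels the matching
score is evaluated as a diagnostic test: confusion matrix at a score
threshold (a regimen is predicted favorable when its score strictly
exceeds the threshold), sensitivity/specificity/PPV/NPV with exact
Clopper–Pearson confidence intervals, the ROC curve with the
rank-statistic (Mann–Whitney) AUC, Youden-index threshold selection, and
the Mann–Whitney U comparison of score distributions between the two
outcome groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .scoring import Regimen, round_half_up

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD")

SUCCESSFUL = "successful"
UNSUCCESSFUL = "unsuccessful"

#: Outcome categories used in cohort summaries.
CATEGORY_CR = "complete_response"
CATEGORY_PR_SD12 = "partial_response_or_sd_ge_12m"
CATEGORY_SD_6_12 = "sd_6_to_12m"
CATEGORY_PD_SD6 = "pd_or_sd_lt_6m"


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment line: regimen, RECIST response, and duration."""

    patient_id: str
    regimen: Regimen
    response: str
    ttf_months: float
    score_percent: int | None = None

    def __post_init__(self):
        if self.response not in RESPONSE_CLASSES:
            raise ValidationError(
                f"response must be one of {RESPONSE_CLASSES}, got {self.response!r}",
                field="response",
            )
        if self.ttf_months < 0:
            raise ValidationError("ttf_months must be non-negative", field="ttf_months")


def classify_outcome(record: TreatmentRecord) -> str:
    """Binary outcome label of a treatment line.

    CR and PR are successes regardless of duration; SD is a success only
    when it lasted >= 12 months; PD is always a failure.
    """
    if record.response in ("CR", "PR"):
        return SUCCESSFUL
    if record.response == "SD" and record.ttf_months >= 12:
        return SUCCESSFUL
    return UNSUCCESSFUL


def outcome_category(record: TreatmentRecord) -> str:
    """Four-way outcome category used in cohort description tables."""
    if record.response == "CR":
        return CATEGORY_CR
    if record.response == "PR" or (record.response == "SD" and record.ttf_months >= 12):
        return CATEGORY_PR_SD12
    if record.response == "SD" and 6 <= record.ttf_months < 12:
        return CATEGORY_SD_6_12
    return CATEGORY_PD_SD6


def summarize_outcomes(records: Iterable[TreatmentRecord]) -> dict:
    """Counts per outcome category and per binary label.

    Category counts always sum to the number of records; the successful
    label count equals CR plus PR/SD>=12, the unsuccessful count the
    remaining two categories.
    """
    categories = {
        CATEGORY_CR: 0,
        CATEGORY_PR_SD12: 0,
        CATEGORY_SD_6_12: 0,
        CATEGORY_PD_SD6: 0,
    }
    labels = {SUCCESSFUL: 0, UNSUCCESSFUL: 0}
    n = 0
    for rec in records:
        categories[outcome_category(rec)] += 1
        labels[classify_outcome(rec)] += 1
        n += 1
    return {"n": n, "categories": categories, "labels": labels}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold_percent: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_label_array(labels: Sequence) -> np.ndarray:
    arr = np.asarray(
        [1 if l in (1, True, SUCCESSFUL) else 0 for l in labels], dtype=int
    )
    return arr


def confusion_at_threshold(
    scores: Sequence[float],
    labels: Sequence,
    threshold_percent: float,
    strict: bool = True,
) -> ConfusionMatrix:
    """Confusion matrix of the rule "favorable iff score > threshold".

    The comparison is strict by default: with integer percentage scores
    and a 25% operating point, a score of exactly 25 is predicted
    unfavorable. Pass ``strict=False`` for >=.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    if len(scores) != len(y):
        raise ValidationError(
            f"scores and labels differ in length ({len(scores)} vs {len(y)})"
        )
    pred = scores > threshold_percent if strict else scores >= threshold_percent
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, threshold_percent=threshold_percent)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact (Clopper–Pearson) 95% interval."""

    value: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> int:
        return round_half_up(100 * self.value)

    @property
    def ci_percent(self) -> tuple[int, int]:
        return round_half_up(100 * self.ci_low), round_half_up(100 * self.ci_high)


def _proportion(successes: int, total: int, alpha: float) -> MetricEstimate | None:
    if total == 0:
        return None
    lo, hi = proportion_confint(successes, total, alpha=alpha, method="beta")
    return MetricEstimate(value=successes / total, ci_low=float(lo), ci_high=float(hi))


def performance_metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> dict:
    """Sensitivity, specificity, PPV and NPV with Clopper–Pearson CIs.

    A metric whose denominator is zero is reported as ``None`` (flagged
    undefined) rather than propagating NaN.
    """
    return {
        "sensitivity": _proportion(cm.tp, cm.tp + cm.fn, alpha),
        "specificity": _proportion(cm.tn, cm.tn + cm.fp, alpha),
        "ppv": _proportion(cm.tp, cm.tp + cm.fp, alpha),
        "npv": _proportion(cm.tn, cm.tn + cm.fn, alpha),
    }


@dataclass(frozen=True)
class MannWhitneyResult:
    """Both orientations of U plus the conventional (smaller) statistic."""

    u_successful: float  # pairs where a successful score exceeds an unsuccessful one
    u_unsuccessful: float
    u: float  # min of the two, the conventionally reported statistic
    p_value: float
    method: str


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments (handles ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2  # U of sample x
    mean = n1 * len(y) / 2
    count = 0
    total = comb(len(pooled), n1)
    idx = np.arange(len(pooled))
    for subset in itertools.combinations(idx, n1):
        u = np.sum(ranks[list(subset)]) - n1 * (n1 + 1) / 2
        if abs(u - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def mann_whitney(
    successful_scores: Sequence[float],
    unsuccessful_scores: Sequence[float],
    method: str = "auto",
) -> MannWhitneyResult:
    """Mann–Whitney U comparison of the two score samples.

    U is computed by rank sums with midranks for ties. The p-value uses
    the tie-corrected normal approximation, except that for small
    problems (n1·n2 <= 100) ``method="auto"`` switches to exact
    enumeration of all group assignments, which remains valid under
    ties. The reported ``u`` is the smaller of the two orientations.
    """
    x = np.asarray(successful_scores, dtype=float)
    y = np.asarray(unsuccessful_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u_succ = float(res.statistic)
    u_unsucc = len(x) * len(y) - u_succ
    if method == "auto":
        method = "exact" if len(x) * len(y) <= 100 else "asymptotic"
    if method == "exact":
        p = _exact_mann_whitney_p(x, y)
    elif method == "asymptotic":
        p = float(res.pvalue)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return MannWhitneyResult(
        u_successful=u_succ,
        u_unsuccessful=u_unsucc,
        u=min(u_succ, u_unsucc),
        p_value=p,
        method=method,
    )


@dataclass(frozen=True)
class ROCResult:
    #: (threshold, tpr, fpr) triples ordered by decreasing threshold
    points: tuple[tuple[float, float, float], ...]
    auc: float
    auc_p: float


def roc_and_auc(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """ROC curve and rank-statistic AUC.

    The AUC is computed through the Mann–Whitney identity
    ``AUC = U_successful / (n1 · n2)`` with tied pairs counted 1/2; its
    p-value is the tie-corrected normal approximation of U. The curve
    points come from all distinct score thresholds.
    """
    y = _as_label_array(labels)
    scores = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("roc_and_auc requires at least one of each label")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    res = stats.mannwhitneyu(
        scores[y == 1], scores[y == 0], alternative="two-sided", method="asymptotic"
    )
    n1 = int(y.sum())
    n2 = len(y) - n1
    auc = float(res.statistic) / (n1 * n2)
    points = tuple(
        (float(t), float(tp_), float(fp_)) for t, tp_, fp_ in zip(thresholds, tpr, fpr)
    )
    return ROCResult(points=points, auc=auc, auc_p=float(res.pvalue))


def youden_threshold(
    scores: Sequence[float], labels: Sequence, strict: bool = True
) -> float:
    """Operating threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the distinct observed scores plus one value
    below the minimum (the classify-everything-favorable rule); ties are
    broken toward the lowest threshold.
    """
    y = _as_label_array(labels)
    scores = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("youden_threshold requires at least one of each label")
    candidates = sorted(set(scores.tolist()))
    candidates = [candidates[0] - 1.0] + candidates
    best_t, best_j = None, -np.inf
    for t in candidates:
        cm = confusion_at_threshold(scores, y, t, strict=strict)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t)


# ---------------------------------------------------------------------------
# Cohort table IO
# ---------------------------------------------------------------------------

def load_cohort(path) -> list[TreatmentRecord]:
    """Read a cohort TSV (patient_id, regimen, response, ttf_months[, score_percent])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for i, row in df.iterrows():
        score = row.get("score_percent")
        records.append(
            TreatmentRecord(
                patient_id=str(row["patient_id"]),
                regimen=Regimen.parse(str(row["regimen"])),
                response=str(row["response"]),
                ttf_months=float(row["ttf_months"]),
                score_percent=None if pd.isna(score) else int(score),
            )
        )
    return records


def write_cohort(records: Sequence[TreatmentRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "regimen": r.regimen.label,
                "response": r.response,
                "ttf_months": r.ttf_months,
                "score_percent": r.score_percent,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def evaluate_cohort(
    records: Sequence[TreatmentRecord],
    threshold_percent: float = 25.0,
    strict: bool = True,
) -> dict:
    """Full validation report for a scored cohort.

    Returns outcome summary, confusion matrix and metrics at the given
    threshold, ROC/AUC, the Youden-optimal threshold, and the
    Mann–Whitney comparison of successful vs unsuccessful score
    distributions.
    """
    scores = np.array([r.score_percent for r in records], dtype=float)
    if np.any(np.isnan(scores)):
        raise ValidationError("all records must carry a score_percent")
    labels = [classify_outcome(r) for r in records]
    y = _as_label_array(labels)
    cm = confusion_at_threshold(scores, y, threshold_percent, strict=strict)
    roc = roc_and_auc(scores, y)
    mw = mann_whitney(scores[y == 1], scores[y == 0])
    return {
        "summary": summarize_outcomes(records),
        "threshold_percent": threshold_percent,
        "confusion": cm,
        "metrics": performance_metrics(cm),
        "roc": roc,
        "youden_threshold": youden_threshold(scores, y, strict=strict),
        "mann_whitney": mw,
        "median_score_successful": float(np.median(scores[y == 1])),
        "median_score_unsuccessful": float(np.median(scores[y == 0])),
        "mean_score_successful": float(np.mean(scores[y == 1])),
        "mean_score_unsuccessful": float(np.mean(scores[y == 0])),
    }
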