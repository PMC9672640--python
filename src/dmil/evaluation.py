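"""Clinical evaluation of bag scores: confusion metrics, ROC/AUC with
confidence intervals, operating-point selection and decision-curve analysis.

Conventions
-----------
* Scores are probabilities of the positive class (label 1 = response).
* A bag is called positive when ``score >= cutoff`` (closed on the left).
* AUC is the trapezoidal area of the empirical ROC, equal to the
  Mann-Whitney probability with half-credit for tied scores.
* The default AUC confidence interval is DeLong's nonparametric estimator
  with a normal approximation; a percentile bootstrap is available.
* Net benefit at threshold probability ``p`` is
  ``NB(p) = TP/N - (FP/N) * p / (1 - p)``; the treat-all policy has
  ``NB = pi - (1 - pi) * p / (1 - p)`` (``pi`` = prevalence) and treat-none
  is identically zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ScoredCohort",
    "ConfusionMetrics",
    "RocCurve",
    "EvalReport",
    "DCACurve",
    "confusion_metrics",
    "roc_auc",
    "auc_ci",
    "optimal_cutoffs",
    "decision_curve",
    "evaluate_cohort",
]


@dataclass
class ScoredCohort:
    """Bag scores with binary labels; the unit of every evaluation op."""

    bag_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.bag_ids = [str(b) for b in self.bag_ids]
        n = len(self.bag_ids)
        if self.scores.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("bag_ids, scores and labels must have equal length")
        if n == 0:
            raise ValueError("cohort is empty")
        if np.any(self.scores < -1e-9) or np.any(self.scores > 1 + 1e-9):
            raise ValueError("scores must lie in [0, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bag_ids)

    @property
    def has_both_classes(self) -> bool:
        return 0 < self.labels.sum() < len(self)

    @classmethod
    def from_records(cls, records) -> "ScoredCohort":
        ids, scores, labels = zip(*records)
        return cls(list(ids), np.array(scores), np.array(labels))

    @classmethod
    def from_csv(cls, path) -> "ScoredCohort":
        df = pd.read_csv(path)
        missing = {"bag_id", "score", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"scores CSV missing columns: {sorted(missing)}")
        return cls(df["bag_id"].tolist(), df["score"].to_numpy(),
                   df["label"].to_numpy())

    def flipped(self) -> "ScoredCohort":
        """Swap the positive-class convention (labels and scores)."""
        return ScoredCohort(self.bag_ids, 1.0 - self.scores, 1 - self.labels)


@dataclass
class ConfusionMetrics:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class EvalReport:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    ci_level: float
    cutoff_youden: float
    cutoff_min_distance: float
    n: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["auc_ci"] = list(self.auc_ci)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class DCACurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_treat_all": self.nb_treat_all,
                "nb_treat_none": self.nb_treat_none,
            }
        )


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator for {what}; reporting 0")
        return 0.0
    return num / den


def confusion_metrics(cohort: ScoredCohort, cutoff: float) -> ConfusionMetrics:
    """Confusion counts and rates at a fixed cutoff (positive: score >= cutoff)."""
    pred = cohort.scores >= cutoff
    truth = cohort.labels == 1
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    n = len(cohort)
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "sensitivity")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    return ConfusionMetrics(
        cutoff=float(cutoff),
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=recall,
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        f1=f1,
    )


def roc_auc(cohort: ScoredCohort) -> RocCurve:
    """Empirical ROC over all score thresholds plus sentinels, with AUC."""
    if not cohort.has_both_classes:
        raise ValueError("ROC requires both classes in the cohort")
    fpr, tpr, thr = roc_curve(
        cohort.labels, cohort.scores, drop_intermediate=False
    )
    auc = float(roc_auc_score(cohort.labels, cohort.scores))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative score samples."""

    def midrank(x: np.ndarray) -> np.ndarray:
        # average rank (1-based) with ties sharing their mean rank
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    m, n = len(pos), len(neg)
    allx = np.concatenate([pos, neg])
    tx = midrank(pos)
    ty = midrank(neg)
    tz = midrank(allx)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def auc_ci(
    cohort: ScoredCohort,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` (default) uses the nonparametric DeLong variance with
    a normal approximation; ``method="bootstrap"`` uses a percentile bootstrap
    over cohort resamples.
    """
    if not cohort.has_both_classes:
        raise ValueError("AUC CI requires both classes")
    pos = cohort.scores[cohort.labels == 1]
    neg = cohort.scores[cohort.labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("AUC CI requires at least two items per class")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "delong":
        auc, var = _delong_variance(pos, neg)
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(max(var, 0.0))
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(cohort)
        aucs = []
        while len(aucs) < n_boot:
            idx = rng.integers(0, n, n)
            lab = cohort.labels[idx]
            if 0 < lab.sum() < n:
                aucs.append(roc_auc_score(lab, cohort.scores[idx]))
        lo, hi = np.quantile(aucs, [0.5 - level / 2, 0.5 + level / 2])
        return (max(0.0, float(lo)), min(1.0, float(hi)))
    raise ValueError(f"unknown CI method {method!r}")


def optimal_cutoffs(roc: RocCurve) -> tuple[float, float]:
    """Youden-index and minimum-distance-to-(0,1) cut-offs from an ROC.

    Ties are broken toward the lower threshold value.
    """
    sens, spec = roc.tpr, 1.0 - roc.fpr
    youden = sens + spec - 1.0
    dist = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)

    def pick(values: np.ndarray, best_is_max: bool) -> float:
        target = values.max() if best_is_max else values.min()
        candidates = roc.thresholds[np.isclose(values, target)]
        return float(candidates.min())

    return pick(youden, True), pick(dist, False)


def decision_curve(
    cohort: ScoredCohort, thresholds: np.ndarray | None = None
) -> DCACurve:
    """Net benefit of the model vs. treat-all and treat-none policies."""
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(cohort)
    truth = cohort.labels == 1
    prevalence = truth.mean()
    odds = thresholds / (1.0 - thresholds)
    pred = cohort.scores[None, :] >= thresholds[:, None]
    tp = (pred & truth[None, :]).sum(axis=1)
    fp = (pred & ~truth[None, :]).sum(axis=1)
    nb_model = tp / n - (fp / n) * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DCACurve(
        thresholds=thresholds,
        nb_model=nb_model,
        nb_treat_all=nb_all,
        nb_treat_none=np.zeros_like(thresholds),
    )


def evaluate_cohort(
    cohort: ScoredCohort,
    cutoff: float | str = "youden",
    ci_level: float = 0.95,
    ci_method: str = "delong",
    positive_label: int = 1,
) -> EvalReport:
    """Full evaluation panel at a fixed or ROC-derived cutoff.

    ``cutoff`` may be a number, ``"youden"`` or ``"min_distance"``.
    ``positive_label=0`` flips the class convention (scores become 1 - score).
    """
    if positive_label == 0:
        cohort = cohort.flipped()
    elif positive_label != 1:
        raise ValueError("positive_label must be 0 or 1")
    roc = roc_auc(cohort)
    cut_y, cut_d = optimal_cutoffs(roc)
    if cutoff == "youden":
        cut = cut_y
    elif cutoff == "min_distance":
        cut = cut_d
    else:
        cut = float(cutoff)
    cm = confusion_metrics(cohort, cut)
    lo, hi = auc_ci(cohort, level=ci_level, method=ci_method)
    return EvalReport(
        cutoff=cut,
        tp=cm.tp, fp=cm.fp, tn=cm.tn, fn=cm.fn,
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        f1=cm.f1,
        auc=roc.auc,
        auc_ci=(lo, hi),
        ci_level=ci_level,
        cutoff_youden=cut_y,
        cutoff_min_distance=cut_d,
        n=len(cohort),
    )
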