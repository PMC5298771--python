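"""Trial-level threshold classification and cross-validated evaluation.

Each trial is reduced to a single score — the maximum of its feature
series — and compared against a threshold: the trial is called a fall iff
its score strictly exceeds the threshold (ties go to ADL, since the
sensitivity-first threshold sits "just below" the minimum fall score).

Two threshold policies:

* **T1** maximizes training accuracy AC = (SE + SP) / 2, scanned over the
  midpoints of consecutive distinct sorted scores plus outer sentinels
  (AC is piecewise constant, so the scan is exhaustive). Ties resolve to
  the highest-sensitivity candidate, then the lowest threshold.
* **T2** maximizes sensitivity: it sits just below the minimum training
  fall score, so training SE = 1 by construction.

Metrics: SE = TP/(TP+FN), SP = TN/(TN+FP), AC = (SE+SP)/2 — the
arithmetic mean accommodates unbalanced class counts. Validation uses
class-stratified k-fold cross-validation (default k = 10) preserving the
fall/ADL proportion per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureSeries, WindowSpec

__all__ = [
    "TrialScore",
    "ThresholdModel",
    "ConfusionCounts",
    "EvaluationResult",
    "UndefinedMetricError",
    "trial_score",
    "classify",
    "confusion",
    "metrics",
    "fit_t1",
    "fit_t2",
    "fit_threshold",
    "stratified_kfold",
    "cross_validate",
    "transfer_evaluate",
]

#: relative epsilon placing T2 "just below" the minimum fall score
T2_EPS = 1e-6


class UndefinedMetricError(ValueError):
    """A metric's denominator class is empty."""


@dataclass(frozen=True)
class TrialScore:
    trial_id: str
    feature: str
    score: float
    label: str  # "fall" | "adl"
    cohort: str = "unknown"
    subject: str = ""
    activity: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("fall", "adl"):
            raise ValueError(f"label must be 'fall' or 'adl', got {self.label!r}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class ThresholdModel:
    feature: str
    policy: str  # "T1" | "T2"
    threshold: float
    filtered: bool = False
    window: WindowSpec | None = None

    def __post_init__(self) -> None:
        if self.policy not in ("T1", "T2"):
            raise ValueError(f"policy must be 'T1' or 'T2', got {self.policy!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def trial_score(
    series: FeatureSeries,
    label: str,
    trial_id: str,
    *,
    cohort: str = "unknown",
    subject: str = "",
    activity: str = "",
) -> TrialScore:
    """Reduce a feature series to its trial-level score (the maximum)."""
    return TrialScore(
        trial_id=trial_id,
        feature=series.code,
        score=series.max(),
        label=label,
        cohort=cohort,
        subject=subject,
        activity=activity,
    )


def classify(score: TrialScore | float, model: ThresholdModel) -> str:
    """Fall iff the score strictly exceeds the threshold."""
    if isinstance(score, TrialScore):
        if score.feature != model.feature:
            raise ValueError(
                f"feature mismatch: score is {score.feature}, model is {model.feature}"
            )
        value = score.score
    else:
        value = float(score)
    return "fall" if value > model.threshold else "adl"


def _arrays(scores: Sequence[TrialScore]) -> tuple[np.ndarray, np.ndarray]:
    values = np.array([s.score for s in scores], dtype=float)
    is_fall = np.array([s.label == "fall" for s in scores], dtype=bool)
    return values, is_fall


def confusion(scores: Sequence[TrialScore], model: ThresholdModel) -> ConfusionCounts:
    values, is_fall = _arrays(scores)
    pred = values > model.threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & is_fall)),
        tn=int(np.sum(~pred & ~is_fall)),
        fp=int(np.sum(pred & ~is_fall)),
        fn=int(np.sum(~pred & is_fall)),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and their arithmetic mean (accuracy)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("no fall trials: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("no ADL trials: specificity undefined")
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return se, sp, (se + sp) / 2.0


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    spread = distinct[-1] - distinct[0]
    pad = max(spread, 1.0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - pad], mids, [distinct[-1] + pad]))


def fit_t1(
    scores: Sequence[TrialScore],
    *,
    filtered: bool = False,
    window: WindowSpec | None = None,
) -> ThresholdModel:
    """Maximum-accuracy threshold by exhaustive scan over score midpoints.

    Tie-break among equal-accuracy candidates: highest sensitivity, then
    lowest threshold.
    """
    values, is_fall = _arrays(scores)
    n_fall = int(is_fall.sum())
    n_adl = len(values) - n_fall
    if n_fall == 0 or n_adl == 0:
        raise ValueError("T1 fitting needs both classes in the training scores")

    falls = np.sort(values[is_fall])
    adls = np.sort(values[~is_fall])
    cands = _candidate_thresholds(values)
    tp = n_fall - np.searchsorted(falls, cands, side="right")
    fp = n_adl - np.searchsorted(adls, cands, side="right")
    se = tp / n_fall
    sp = (n_adl - fp) / n_adl
    ac = (se + sp) / 2.0

    best_ac = ac.max()
    tie = np.flatnonzero(ac == best_ac)
    tie = tie[se[tie] == se[tie].max()]
    threshold = float(cands[tie].min())
    return ThresholdModel(
        feature=scores[0].feature, policy="T1", threshold=threshold,
        filtered=filtered, window=window,
    )


def fit_t2(
    scores: Sequence[TrialScore],
    *,
    filtered: bool = False,
    window: WindowSpec | None = None,
) -> ThresholdModel:
    """Maximum-sensitivity threshold: just below the minimum fall score."""
    values, is_fall = _arrays(scores)
    if not is_fall.any():
        raise ValueError("T2 fitting needs at least one fall in the training scores")
    spread = values.max() - values.min()
    scale = spread if spread > 0 else max(abs(values.min()), 1.0)
    threshold = float(values[is_fall].min() - T2_EPS * scale)
    return ThresholdModel(
        feature=scores[0].feature, policy="T2", threshold=threshold,
        filtered=filtered, window=window,
    )


def fit_threshold(scores: Sequence[TrialScore], policy: str, **kw) -> ThresholdModel:
    if policy == "T1":
        return fit_t1(scores, **kw)
    if policy == "T2":
        return fit_t2(scores, **kw)
    raise ValueError(f"unknown policy {policy!r}")


def stratified_kfold(
    labels: Sequence[str], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Class-stratified fold assignment (0..k-1 per trial).

    Preserves the fall/ADL proportion per fold to within one trial;
    deterministic for a given seed.
    """
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class EvaluationResult:
    """Per-fold confusion counts and metrics with mean +/- std summaries."""

    fold_counts: list[ConfusionCounts]
    fold_se: np.ndarray
    fold_sp: np.ndarray
    fold_ac: np.ndarray
    thresholds: np.ndarray
    policy: str
    feature: str
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.fold_counts)

    def _summary(self, arr: np.ndarray) -> tuple[float, float]:
        ddof = 1 if len(arr) > 1 else 0
        return float(np.mean(arr)), float(np.std(arr, ddof=ddof))

    @property
    def se(self) -> tuple[float, float]:
        return self._summary(self.fold_se)

    @property
    def sp(self) -> tuple[float, float]:
        return self._summary(self.fold_sp)

    @property
    def ac(self) -> tuple[float, float]:
        return self._summary(self.fold_ac)

    @property
    def threshold(self) -> tuple[float, float]:
        return self._summary(self.thresholds)

    def summary(self) -> str:
        (mse, sse), (msp, ssp), (mac, sac) = self.se, self.sp, self.ac
        return (
            f"{self.feature} {self.policy}: "
            f"SE {100 * mse:.2f} ± {100 * sse:.2f}%, "
            f"SP {100 * msp:.2f} ± {100 * ssp:.2f}%, "
            f"AC {100 * mac:.2f} ± {100 * sac:.2f}%"
        )


def _evaluate_counts(counts: ConfusionCounts) -> tuple[float, float, float]:
    return metrics(counts)


def cross_validate(
    scores: Sequence[TrialScore],
    policy: str = "T1",
    k: int = 10,
    seed: int = 0,
    config: dict | None = None,
) -> EvaluationResult:
    """k-fold cross-validation: fit the threshold on k-1 folds, score the
    held-out fold with Eq.-style metrics, summarize across folds."""
    scores = list(scores)
    labels = [s.label for s in scores]
    folds = stratified_kfold(labels, k=k, seed=seed)
    fold_counts, fse, fsp, fac, thr = [], [], [], [], []
    for fold in range(k):
        train = [s for s, f in zip(scores, folds) if f != fold]
        test = [s for s, f in zip(scores, folds) if f == fold]
        model = fit_threshold(train, policy)
        counts = confusion(test, model)
        se, sp, ac = metrics(counts)
        fold_counts.append(counts)
        fse.append(se)
        fsp.append(sp)
        fac.append(ac)
        thr.append(model.threshold)
    return EvaluationResult(
        fold_counts=fold_counts,
        fold_se=np.array(fse),
        fold_sp=np.array(fsp),
        fold_ac=np.array(fac),
        thresholds=np.array(thr),
        policy=policy,
        feature=scores[0].feature,
        config=dict(config or {}, k=k, seed=seed),
    )


def transfer_evaluate(
    train_scores: Sequence[TrialScore],
    test_scores: Sequence[TrialScore],
    policy: str = "T1",
    config: dict | None = None,
) -> EvaluationResult:
    """Single fit on the training cohort, single evaluation on the test
    cohort (the young-to-elderly transfer protocol)."""
    train_scores = list(train_scores)
    test_scores = list(test_scores)
    if not train_scores or not test_scores:
        raise ValueError("transfer evaluation needs nonempty train and test sets")
    model = fit_threshold(train_scores, policy)
    counts = confusion(test_scores, model)
    se, sp, ac = metrics(counts)
    return EvaluationResult(
        fold_counts=[counts],
        fold_se=np.array([se]),
        fold_sp=np.array([sp]),
        fold_ac=np.array([ac]),
        thresholds=np.array([model.threshold]),
        policy=policy,
        feature=train_scores[0].feature,
        config=dict(config or {}),
    )
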