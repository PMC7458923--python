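"""Repeated stratified random-forest importance-stability protocol.

The question this protocol answers is not "how accurate is one forest?" but
"which compounds does the forest *consistently* rely on?".  For each of
``n_runs`` replicates the data are split 50/50 (stratified by species), a
forest is fit on the training half, classification metrics are measured on
the held-out half, and the single compound with the highest mean decrease in
Gini impurity is tallied.  Aggregation yields the top-importance frequency
table, a chi-square test of uniform pick probability over the compounds ever
picked, averaged classification metrics (accuracy with exact binomial 95%
bounds, Cohen's kappa, sensitivity, specificity), and a pooled ROC curve
with its trapezoidal AUC.

The tree learner is scikit-learn's RandomForestClassifier (bootstrap per
tree, ``mtry`` random candidate variables per split, Gini impurity,
majority voting); the protocol around it — tuning by out-of-bag error,
stratified splitting, tallying, the chi-square test, metric averaging and
the pooled ROC — is implemented here.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .profile_io import CompoundTable, ProfileError

logger = logging.getLogger(__name__)


@dataclass
class RFProtocolConfig:
    n_runs: int = 1000
    train_fraction: float = 0.5
    n_trees: int = 500
    mtry: int = 17
    positive_class: str = "marthae"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ProfileError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ProfileError("n_runs must be >= 1")


@dataclass
class RunOutcome:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    top_importance_compound: str
    scores: np.ndarray  # per-test-sample positive-class vote fraction
    labels: np.ndarray  # matching binary truth (1 = positive class)


@dataclass
class StabilityResult:
    frequency: dict[str, int]
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    mean_metrics: dict[str, float]
    roc_points: np.ndarray  # (m, 2) of (FPR, TPR)
    auc: float
    runs: list[RunOutcome] = field(repr=False, default_factory=list)
    n_discarded: int = 0

    def frequency_frame(self) -> pd.DataFrame:
        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["compound_id", "count"])


def chi2_uniform(counts: Sequence[float]) -> tuple[float, int, float]:
    """Chi-square test of uniform pick probability over ``k`` categories
    (expected count n/k each).  The caller chooses the category universe;
    zero counts are allowed.  Returns (statistic, df, p)."""
    counts = np.asarray(counts, dtype=float)
    k = len(counts)
    if k < 2:
        return 0.0, 0, 1.0
    stat, p = stats.chisquare(counts)
    return float(stat), k - 1, float(p)


def kappa_from_confusion(tp: float, fp: float, tn: float, fn: float) -> float:
    """Cohen's kappa from a 2x2 confusion table (fractional counts allowed).

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp + tn)/N and chance agreement
    p_e = [(tp+fp)(tp+fn) + (tn+fn)(tn+fp)] / N^2.
    """
    n = tp + fp + tn + fn
    if n <= 0:
        raise ProfileError("empty confusion table")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    if p_e >= 1.0:
        warnings.warn("degenerate confusion table: chance agreement is 1")
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence bounds for a proportion."""
    if n <= 0:
        raise ProfileError("empty sample for confidence interval")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def stratified_split(
    labels: Sequence, train_fraction: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split preserving class
    proportions.  Per class the train count is round(n * fraction) with
    halves rounded up."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for lv in np.unique(labels):
        idx = np.nonzero(labels == lv)[0]
        if len(idx) < 2:
            raise ProfileError(f"class {lv!r} has fewer than 2 samples")
        n_train = int(np.floor(len(idx) * train_fraction + 0.5))
        if n_train == 0 or n_train == len(idx):
            raise ProfileError(
                f"train_fraction {train_fraction} empties a split for class {lv!r}"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep over the unique scores (ties share a
    threshold); AUC by the trapezoidal rule.  ``labels`` are 1 for the
    positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ProfileError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.nonzero(np.diff(s))[0]
    bounds = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[bounds]
    fps = np.cumsum(1 - y)[bounds]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def tune(
    table: CompoundTable,
    labels: Sequence,
    grid: Sequence[tuple[int, int]],
    seed: int = 0,
) -> tuple[int, int]:
    """Pick (n_trees, mtry) minimizing out-of-bag error on the full data.
    Ties break toward smaller mtry, then smaller n_trees."""
    if not grid:
        raise ProfileError("empty tuning grid")
    p = table.n_compounds
    for n_trees, mtry in grid:
        if mtry > p:
            raise ProfileError(f"mtry {mtry} exceeds compound count {p}")
    y = np.asarray(labels)
    results = []
    for n_trees, mtry in grid:
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry, oob_score=True,
            bootstrap=True, random_state=seed, n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse OOB coverage at tiny n_trees
            clf.fit(table.abundances, y)
        oob_error = 1.0 - clf.oob_score_
        results.append((oob_error, mtry, n_trees))
        logger.info("tune: n_trees=%d mtry=%d oob_error=%.4f", n_trees, mtry, oob_error)
    results.sort()
    _, mtry, n_trees = results[0]
    return n_trees, mtry


def _top_importance(importances: np.ndarray, compound_ids: list[str]) -> str:
    best = importances.max()
    tied = [compound_ids[j] for j in np.nonzero(importances == best)[0]]
    if len(tied) > 1:
        warnings.warn(f"importance tie broken lexicographically among {tied}")
    return min(tied)


def run_protocol(
    table: CompoundTable, labels: Sequence, config: RFProtocolConfig
) -> StabilityResult:
    """Execute the full repeated-split protocol.  Bit-reproducible for a
    fixed master seed (child seeds are drawn from one deterministic stream);
    a run whose test set collapses to one class is discarded, logged, and
    replaced."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ProfileError(f"binary labels required, got {list(classes)}")
    if config.positive_class not in classes:
        raise ProfileError(f"positive class {config.positive_class!r} absent")
    if config.mtry > table.n_compounds:
        raise ProfileError("mtry exceeds compound count")

    seed_stream = np.random.default_rng(config.master_seed)
    runs: list[RunOutcome] = []
    n_discarded = 0
    max_attempts = 10 * config.n_runs + 100
    attempts = 0
    while len(runs) < config.n_runs:
        attempts += 1
        if attempts > max_attempts:
            raise ProfileError("too many degenerate runs discarded")
        split_seed = int(seed_stream.integers(2**31))
        tree_seed = int(seed_stream.integers(2**31))
        train, test = stratified_split(y, config.train_fraction, split_seed)
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            n_discarded += 1
            logger.warning("discarding degenerate single-class split")
            continue
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.mtry,
            bootstrap=True,
            random_state=tree_seed,
            n_jobs=1,
        )
        clf.fit(table.abundances[train], y[train])
        pos_col = list(clf.classes_).index(config.positive_class)
        votes = clf.predict_proba(table.abundances[test])[:, pos_col]
        pred_pos = clf.predict(table.abundances[test]) == config.positive_class
        true_pos = y[test] == config.positive_class
        tp = int(np.sum(pred_pos & true_pos))
        fp = int(np.sum(pred_pos & ~true_pos))
        tn = int(np.sum(~pred_pos & ~true_pos))
        fn = int(np.sum(~pred_pos & true_pos))
        n_test = len(test)
        acc = (tp + tn) / n_test
        ci_low, ci_high = clopper_pearson(tp + tn, n_test)
        runs.append(
            RunOutcome(
                tp=tp, fp=fp, tn=tn, fn=fn,
                accuracy=acc,
                kappa=kappa_from_confusion(tp, fp, tn, fn),
                sensitivity=tp / (tp + fn) if tp + fn else np.nan,
                specificity=tn / (tn + fp) if tn + fp else np.nan,
                ci_low=ci_low, ci_high=ci_high,
                top_importance_compound=_top_importance(
                    clf.feature_importances_, table.compound_ids
                ),
                scores=votes,
                labels=true_pos.astype(int),
            )
        )

    freq = Counter(r.top_importance_compound for r in runs)
    counts = np.array(sorted(freq.values(), reverse=True))
    # category universe = compounds ever observed as top-1
    chi2_stat, chi2_df, chi2_p = chi2_uniform(counts)
    mean_metrics = {
        name: float(np.mean([getattr(r, name) for r in runs]))
        for name in ("accuracy", "kappa", "sensitivity", "specificity", "ci_low", "ci_high")
    }
    pooled_scores = np.concatenate([r.scores for r in runs])
    pooled_labels = np.concatenate([r.labels for r in runs])
    roc_points, auc = roc_auc(pooled_scores, pooled_labels)
    return StabilityResult(
        frequency=dict(freq),
        chi2_stat=chi2_stat,
        chi2_df=chi2_df,
        chi2_p=chi2_p,
        mean_metrics=mean_metrics,
        roc_points=roc_points,
        auc=auc,
        runs=runs,
        n_discarded=n_discarded,
    )


def mean_auc_per_run(result: StabilityResult) -> float:
    """Average of per-run AUCs (alternative to the pooled ROC)."""
    aucs = [roc_auc(r.scores, r.labels)[1] for r in result.runs]
    return float(np.mean(aucs))
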