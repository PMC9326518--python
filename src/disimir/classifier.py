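"""Boosted causality classifier and its evaluation machinery.

An AdaBoost ensemble of depth-1 decision trees (1500 rounds, learning
rate 1.0) is trained on the feature table over repeated random
train/test splits: each split places one-third of the causal miRNAs,
and the same fraction of the non-causal ones, in the test set.  Each
miRNA's causality probability is the mean of its out-of-fold
predictions across the splits in which it landed in the test set, so
the headline AUC never scores a miRNA with a model that saw its label.

The report carries the rank-based AUC with a percentile CI over
per-split AUCs, the associated-only AUC (causal versus merely
disease-associated), a decision threshold that minimizes FP + FN
subject to a minimum false-positive count, the resulting confusion
matrix, its hypergeometric enrichment p-value, and mean feature
importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "PredictionReport", "split_train_test",
    "train_and_predict", "averaged_predictions", "roc_auc",
    "select_threshold", "hypergeometric_pvalue", "evaluate",
]


@dataclass
class ModelConfig:
    """Classifier hyper-parameters and the split protocol."""

    n_estimators: int = 1500
    n_splits: int = 100
    test_fraction_causal: float = 1.0 / 3.0
    min_false_positives: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction_causal < 1.0:
            raise ValueError("test_fraction_causal must be in (0, 1)")


@dataclass
class PredictionReport:
    """Everything evaluate() computes, serializable to TSV."""

    probabilities: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    associated_only_auc: float
    threshold: float
    confusion: tuple[int, int, int, int]  # TN, FP, FN, TP
    hypergeom_p: float
    feature_importances: dict[str, float]
    per_split_auc: list[float] = field(default_factory=list, repr=False)

    def metrics_frame(self) -> pd.DataFrame:
        tn, fp, fn, tp = self.confusion
        rows = [
            ("auc", self.auc),
            ("auc_ci_low", self.auc_ci[0]),
            ("auc_ci_high", self.auc_ci[1]),
            ("associated_only_auc", self.associated_only_auc),
            ("threshold", self.threshold),
            ("tn", tn), ("fp", fp), ("fn", fn), ("tp", tp),
            ("hypergeom_p", self.hypergeom_p),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])

    @classmethod
    def from_frames(cls, metrics: pd.DataFrame, probabilities: pd.Series,
                    importances: pd.Series) -> "PredictionReport":
        d = dict(zip(metrics["metric"], metrics["value"]))
        return cls(
            probabilities=probabilities,
            auc=float(d["auc"]),
            auc_ci=(float(d["auc_ci_low"]), float(d["auc_ci_high"])),
            associated_only_auc=float(d["associated_only_auc"]),
            threshold=float(d["threshold"]),
            confusion=(int(d["tn"]), int(d["fp"]), int(d["fn"]),
                       int(d["tp"])),
            hypergeom_p=float(d["hypergeom_p"]),
            feature_importances=dict(importances),
        )


def split_train_test(table: FeatureTable, cfg: ModelConfig,
                     split_seed: int) -> tuple[pd.Index, pd.Index]:
    """One random train/test partition of the feature-table rows.

    Exactly round(f * n_causal) causal rows and round(f * n_noncausal)
    non-causal rows go to test (f = cfg.test_fraction_causal); the
    remainder trains.  Deterministic given ``split_seed``.
    """
    causal = table.index[table["label"] == 1]
    noncausal = table.index[table["label"] == 0]
    if len(causal) < 3:
        raise ValueError("need at least 3 causal rows to split")
    rng = np.random.default_rng(split_seed)
    f = cfg.test_fraction_causal
    n_test_causal = int(round(f * len(causal)))
    n_test_noncausal = int(round(f * len(noncausal)))
    test_c = rng.choice(causal, size=n_test_causal, replace=False)
    test_n = rng.choice(noncausal, size=n_test_noncausal, replace=False)
    test = pd.Index(np.concatenate([test_c, test_n]))
    train = table.index.difference(test, sort=False)
    if (table.loc[train, "label"].nunique() < 2
            or len(test) == 0 or len(train) == 0):
        raise ValueError("degenerate split: a class is empty")
    return train, test


def _make_booster(cfg: ModelConfig, seed: int) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=cfg.n_estimators,
        learning_rate=1.0,
        random_state=seed,
    )


def train_and_predict(train: FeatureTable, test: FeatureTable,
                      cfg: ModelConfig,
                      return_model: bool = False):
    """Fit the boosted stumps on train; return P(causal) per test row."""
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = _make_booster(cfg, cfg.seed)
    model.fit(train[FEATURE_COLUMNS].to_numpy(), y)
    pos = list(model.classes_).index(1)
    probs = model.predict_proba(test[FEATURE_COLUMNS].to_numpy())[:, pos]
    probs = pd.Series(probs, index=test.index, name="probability")
    return (probs, model) if return_model else probs


def averaged_predictions(table: FeatureTable, cfg: ModelConfig,
                         return_details: bool = False):
    """Mean out-of-fold probability per miRNA over cfg.n_splits splits.

    Split s uses seed cfg.seed + s.  A miRNA that never lands in a test
    set (possible but vanishingly rare) gets one extra split whose test
    set is forced to contain it.
    """
    sums = pd.Series(0.0, index=table.index)
    counts = pd.Series(0, index=table.index)
    per_split_auc: list[float] = []
    importances = np.zeros(len(FEATURE_COLUMNS))

    for s in range(cfg.n_splits):
        train_idx, test_idx = split_train_test(table, cfg, cfg.seed + s)
        probs, model = train_and_predict(
            table.loc[train_idx], table.loc[test_idx], cfg,
            return_model=True)
        sums.loc[probs.index] += probs
        counts.loc[probs.index] += 1
        labels = table.loc[test_idx, "label"]
        if labels.nunique() == 2:
            per_split_auc.append(
                float(roc_auc_score(labels, probs.loc[test_idx])))
        importances += model.feature_importances_

    never = counts.index[counts == 0]
    if len(never) > 0:
        logger.warning("%d miRNA(s) never in test; forcing an extra split",
                       len(never))
        train_idx = table.index.difference(never, sort=False)
        if table.loc[train_idx, "label"].nunique() == 2:
            probs = train_and_predict(table.loc[train_idx],
                                      table.loc[never], cfg)
            sums.loc[never] += probs
            counts.loc[never] += 1

    mean = (sums / counts.replace(0, np.nan)).fillna(0.0)
    mean.name = "probability"
    if not return_details:
        return mean
    importances = importances / max(cfg.n_splits, 1)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return mean, per_split_auc, dict(zip(FEATURE_COLUMNS, importances))


def roc_auc(probs: pd.Series | np.ndarray,
            labels: pd.Series | np.ndarray,
            per_split_auc: list[float] | None = None
            ) -> tuple[float, tuple[float, float]]:
    """Rank-based AUC (ties count 1/2) with a 95% percentile CI.

    The CI comes from the empirical 2.5/97.5 percentiles of the
    per-split AUCs when provided, and degenerates to the point estimate
    otherwise.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes")
    auc = float(roc_auc_score(labels, np.asarray(probs, dtype=float)))
    if per_split_auc:
        lo, hi = np.percentile(per_split_auc, [2.5, 97.5])
        return auc, (float(lo), float(hi))
    return auc, (auc, auc)


def select_threshold(probs: pd.Series | np.ndarray,
                     labels: pd.Series | np.ndarray,
                     min_fp: int = 10) -> float:
    """Probability cutoff minimizing FP + FN with at least min_fp FPs.

    Every distinct probability is a candidate cutoff (predict causal at
    prob >= cutoff).  Among candidates with FP >= min_fp the error sum
    is minimized, ties broken toward the larger threshold; if no cutoff
    attains min_fp false positives the constraint is dropped with a
    warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    candidates = np.unique(probs)
    best: tuple[int, float] | None = None
    best_unconstrained: tuple[int, float] | None = None
    n_pos = int((labels == 1).sum())
    for cut in candidates:
        pred = probs >= cut
        fp = int(np.sum(pred & (labels == 0)))
        fn = n_pos - int(np.sum(pred & (labels == 1)))
        err = fp + fn
        key = (err, -cut)
        if best_unconstrained is None or key < (best_unconstrained[0],
                                                -best_unconstrained[1]):
            best_unconstrained = (err, float(cut))
        if fp >= min_fp:
            if best is None or key < (best[0], -best[1]):
                best = (err, float(cut))
    if best is None:
        logger.warning(
            "no cutoff yields %d false positives; using unconstrained "
            "minimizer", min_fp)
        return best_unconstrained[1]
    return best[1]


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    N miRNAs in the population, K truly causal, n predicted positive,
    k of the predictions truly causal.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def evaluate(table: FeatureTable,
             cfg: ModelConfig | None = None) -> PredictionReport:
    """Run the full repeated-split protocol and assemble the report."""
    cfg = cfg or ModelConfig()
    probs, per_split_auc, importances = averaged_predictions(
        table, cfg, return_details=True)
    labels = table["label"]
    auc, ci = roc_auc(probs, labels, per_split_auc)

    assoc = table["is_associated"]
    if labels[assoc].nunique() == 2:
        assoc_auc = float(roc_auc_score(labels[assoc], probs[assoc]))
    else:
        logger.warning("associated subset has one class; AUC undefined")
        assoc_auc = float("nan")

    threshold = select_threshold(probs, labels, cfg.min_false_positives)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    p = hypergeometric_pvalue(len(table), int(labels.sum()), tp + fp, tp)

    return PredictionReport(
        probabilities=probs,
        auc=auc,
        auc_ci=ci,
        associated_only_auc=assoc_auc,
        threshold=threshold,
        confusion=(tn, fp, fn, tp),
        hypergeom_p=p,
        feature_importances=importances,
        per_split_auc=per_split_auc,
    )
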