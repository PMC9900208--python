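"""Logistic-regression training, genome-wide scoring and cross-validation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from netprio.features import FeatureMatrix
from netprio.ingestion import GeneIndex
from netprio.labels import LabelAssignment

logger = logging.getLogger(__name__)

MIN_POSITIVES = 5
MIN_NEGATIVES = 10


class ModelError(RuntimeError):
    """Fatal training problem (too few labels, non-convergence)."""


@dataclass
class ModelResult:
    """Fitted model plus genome-wide scores.

    ``weights`` live in the standardized feature space (the same pipeline is
    used for every model, so weight vectors are comparable across models
    trained on the same feature matrix). ``probabilities`` cover all n network
    genes, labeled or not; ``ranks`` is the 1-based permutation by descending
    probability with ties broken by ascending internal id; ``novel_flag`` is
    True for genes not in the input positives.
    """

    weights: np.ndarray
    intercept: float
    probabilities: np.ndarray
    ranks: np.ndarray
    novel_flag: np.ndarray
    params: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Per-fold and mean cross-validation metrics.

    The headline metric is log2(auPRC / prior), where prior is the held-out
    positive fraction: 0 means chance, each unit is a doubling over chance.
    auROC and precision at the number of held-out positives are reported
    alongside.
    """

    k: int
    fold_auprc: list[float]
    fold_log2_auprc_over_prior: list[float]
    fold_auroc: list[float]
    fold_precision_at_npos: list[float]
    fold_prior: list[float]
    params: dict = field(default_factory=dict)

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.fold_auprc))

    @property
    def mean_log2_auprc_over_prior(self) -> float:
        return float(np.mean(self.fold_log2_auprc_over_prior))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def mean_precision_at_npos(self) -> float:
        return float(np.mean(self.fold_precision_at_npos))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "folds": [
                {
                    "auprc": self.fold_auprc[i],
                    "log2_auprc_over_prior": self.fold_log2_auprc_over_prior[i],
                    "auroc": self.fold_auroc[i],
                    "precision_at_npos": self.fold_precision_at_npos[i],
                    "prior": self.fold_prior[i],
                }
                for i in range(self.k)
            ],
            "mean": {
                "auprc": self.mean_auprc,
                "log2_auprc_over_prior": self.mean_log2_auprc_over_prior,
                "auroc": self.mean_auroc,
                "precision_at_npos": self.mean_precision_at_npos,
            },
            "params": self.params,
        }


def _standardize(X: np.ndarray, train_rows: np.ndarray) -> np.ndarray:
    """Scale all rows by the training rows' mean and std (zero-variance -> 1)."""
    mu = X[train_rows].mean(axis=0)
    sd = X[train_rows].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _sample_weights(y: np.ndarray) -> np.ndarray:
    # inverse class frequency, sklearn's "balanced" convention
    n = len(y)
    n_pos = int(y.sum())
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
    return w


def _fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2_strength: float,
    seed: int,
    balance_classes: bool,
    max_iter: int = 1000,
) -> LogisticRegression:
    sw = _sample_weights(y) if balance_classes else None
    for attempt, iters in enumerate((max_iter, max_iter * 10)):
        clf = LogisticRegression(
            penalty="l2",
            C=1.0 / l2_strength,
            solver="lbfgs",
            max_iter=iters,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y, sample_weight=sw)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            if attempt:
                logger.info("logistic fit converged after raising max_iter to %d", iters)
            return clf
    raise ModelError(
        f"logistic regression failed to converge within {max_iter * 10} iterations "
        f"(n={len(y)}, d={X.shape[1]}, l2_strength={l2_strength})"
    )


def _ranks_desc(probabilities: np.ndarray) -> np.ndarray:
    """1-based ranks by descending probability, ties to the lower internal id."""
    n = len(probabilities)
    order = np.lexsort((np.arange(n), -probabilities))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def train(
    features: FeatureMatrix,
    labels: LabelAssignment,
    l2_strength: float = 1.0,
    seed: int = 0,
    balance_classes: bool = True,
    min_positives: int = MIN_POSITIVES,
) -> ModelResult:
    """Fit the classifier on labeled genes and score every network gene.

    Only positive and negative rows enter the fit; features are standardized
    to mean 0 / variance 1 over those training rows; L2 regularization with
    strength ``l2_strength`` (= 1/C); class imbalance handled by
    inverse-frequency sample weights unless ``balance_classes`` is False.
    Unlabeled and excluded genes still receive probabilities.
    """
    pos = np.array(sorted(labels.positives), dtype=np.int64)
    neg = np.array(sorted(labels.negatives), dtype=np.int64)
    if len(pos) < min_positives:
        raise ModelError(f"need at least {min_positives} positives, got {len(pos)}")
    if len(neg) < MIN_NEGATIVES:
        raise ModelError(f"need at least {MIN_NEGATIVES} negatives, got {len(neg)}")
    train_rows = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    X = _standardize(features.values, train_rows)
    clf = _fit_logistic(X[train_rows], y, l2_strength, seed, balance_classes)
    probabilities = clf.predict_proba(X)[:, 1]
    novel = np.ones(features.n_nodes, dtype=bool)
    novel[pos] = False
    return ModelResult(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        probabilities=probabilities,
        ranks=_ranks_desc(probabilities),
        novel_flag=novel,
        params={
            "l2_strength": l2_strength,
            "seed": seed,
            "balance_classes": balance_classes,
            "n_positives": int(len(pos)),
            "n_negatives": int(len(neg)),
            "feature_kind": features.kind,
        },
    )


def rank_predictions(result: ModelResult, index: GeneIndex) -> pd.DataFrame:
    """Genome-wide prediction table, best rank first.

    Columns: external_id, symbol, probability, rank, known_or_novel.
    """
    n = len(result.probabilities)
    df = pd.DataFrame(
        {
            "external_id": [index.canonical[i] for i in range(n)],
            "symbol": [index.symbols[i] for i in range(n)],
            "probability": result.probabilities,
            "rank": result.ranks,
            "known_or_novel": np.where(result.novel_flag, "novel", "known"),
        }
    )
    return df.sort_values("rank").reset_index(drop=True)


def _precision_at_npos(y_true: np.ndarray, scores: np.ndarray) -> float:
    h = int(y_true.sum())
    if h == 0:
        return float("nan")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return float(y_true[order[:h]].sum() / h)


def cross_validate(
    features: FeatureMatrix,
    labels: LabelAssignment,
    k: int = 5,
    seed: int = 0,
    l2_strength: float = 1.0,
    balance_classes: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation over the labeled genes.

    Each fold trains the full pipeline (standardization included) on k-1
    parts and scores the held-out part. If k exceeds the positive count it is
    reduced with a warning so every fold holds out at least one positive.
    """
    pos = np.array(sorted(labels.positives), dtype=np.int64)
    neg = np.array(sorted(labels.negatives), dtype=np.int64)
    if k > len(pos):
        warnings.warn(
            f"k={k} exceeds positive count {len(pos)}; reducing k to {len(pos)}",
            stacklevel=2,
        )
        k = len(pos)
    if k < 2:
        raise ModelError("cross-validation needs k >= 2 and at least 2 positives")
    rows = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auprc, fold_log2, fold_auroc, fold_prec, fold_prior = [], [], [], [], []
    for train_idx, test_idx in skf.split(rows, y):
        train_rows, test_rows = rows[train_idx], rows[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        X = _standardize(features.values, train_rows)
        clf = _fit_logistic(X[train_rows], y_tr, l2_strength, seed, balance_classes)
        scores = clf.predict_proba(X[test_rows])[:, 1]
        prior = float(y_te.mean())
        auprc = float(average_precision_score(y_te, scores))
        fold_auprc.append(auprc)
        fold_log2.append(float(np.log2(auprc) - np.log2(prior)))
        fold_auroc.append(float(roc_auc_score(y_te, scores)))
        fold_prec.append(_precision_at_npos(y_te, scores))
        fold_prior.append(prior)
    return CVResult(
        k=k,
        fold_auprc=fold_auprc,
        fold_log2_auprc_over_prior=fold_log2,
        fold_auroc=fold_auroc,
        fold_precision_at_npos=fold_prec,
        fold_prior=fold_prior,
        params={"l2_strength": l2_strength, "seed": seed, "balance_classes": balance_classes},
    )
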