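"""Evaluation metrics and 5-fold cross-validation of the full pipeline.

Thresholded metrics (precision, recall, accuracy, Matthews correlation,
F1) are computed from the confusion counts

    PRE = TP / (TP+FP)            REC = TP / (TP+FN)
    ACC = (TP+TN) / total         F1  = 2*PRE*REC / (PRE+REC)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any 0/0 reported as NaN (undefined, deliberately distinct from 0).
The threshold-free summaries are AUPR (step-wise average precision) and
AUC (Mann-Whitney rank statistic with tie correction).

Cross-validation splits the positives and an equal number of sampled
negatives into k folds.  For each fold the held-out positive edges are
(by default) removed from the treat layer before the commuting matrices
and SVD features are rebuilt -- otherwise the treat-layer meta paths would
encode the test labels outright -- then the five base classifiers are
trained on the remaining folds and score the held-out pairs.  Metrics are
pooled over the concatenated test scores; per-fold values are also kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._seeds import derive_seed
from .ensemble import DEFAULT_N_TREES, choose_threshold, train_base
from .features import feature_table, truncated_svd
from .metapaths import MetaPath, all_commuting_matrices
from .negatives import balanced_training_pairs
from .network import HeteroNetwork

CLASSIFIER_NAMES = [f"meta-path-{k}" for k in range(1, 6)] + ["ensemble"]


class ConfusionCounts(NamedTuple):
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


class Metrics(NamedTuple):
    PRE: float
    REC: float
    ACC: float
    MCC: float
    F1: float


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix of the rule ``score > threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not scores.size:
        raise ValueError("cannot tally an empty score vector")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Exact metric formulas; undefined (0/0) values come back as NaN."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    nan = float("nan")
    pre = c.TP / (c.TP + c.FP) if c.TP + c.FP else nan
    rec = c.TP / (c.TP + c.FN) if c.TP + c.FN else nan
    acc = (c.TP + c.TN) / c.total
    den = math.sqrt(float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = (c.TP * c.TN - c.FP * c.FN) / den if den else nan
    if math.isnan(pre) or math.isnan(rec) or pre + rec == 0:
        f1 = nan
    else:
        f1 = 2 * pre * rec / (pre + rec)
    return Metrics(PRE=pre, REC=rec, ACC=acc, MCC=mcc, F1=f1)


def aupr_auc(scores, labels) -> tuple[float, float]:
    """(AUPR, AUC) of a score vector against binary labels.

    AUPR is step-wise average precision; AUC is the probability that a
    random positive outscores a random negative, ties counted half.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to draw PR/ROC curves")
    return (float(average_precision_score(labels, scores)),
            float(roc_auc_score(labels, scores)))


def _partition(items: list, n_folds: int, seed: int) -> list[list]:
    """Seeded shuffle then split into n_folds near-equal parts."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return [[items[i] for i in chunk] for chunk in np.array_split(order, n_folds)]


@dataclass
class EvalReport:
    """Pooled and per-fold performance of the five base classifiers + ensemble."""

    pooled: dict            # classifier name -> {AUPR, AUC, PRE, ..., threshold}
    per_fold: dict          # classifier name -> list of {fold, AUPR, AUC}
    fold_sizes: list
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.pooled, orient="index").loc[CLASSIFIER_NAMES]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"pooled": self.pooled, "per_fold": self.per_fold,
             "fold_sizes": self.fold_sizes, "config": self.config},
            indent=2, sort_keys=True, allow_nan=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("classifier").to_csv(path, sep="\t",
                                                         float_format="%.6f")


def cross_validate(
    network: HeteroNetwork,
    latent_feature_percent: float = 0.03,
    strategy: str = "reliable",
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = DEFAULT_N_TREES,
    mask_test_edges: bool = True,
) -> EvalReport:
    """k-fold cross-validation of the meta-path ensemble on one network.

    Negatives are drawn once (balanced against the positives, under
    ``strategy``) and split into the same folds as the positives, keeping
    fold pair sets disjoint.  With ``mask_test_edges`` (default) each
    fold's held-out positives are removed from the treat layer before the
    commuting matrices and latent features are rebuilt, so no feature can
    see a test label; set it to False to reproduce the naive protocol.
    """
    labeled = balanced_training_pairs(network, strategy,
                                      derive_seed(seed, "negatives"))
    positives, negatives = sorted(labeled.positives), sorted(labeled.negatives)
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive pairs for {n_folds}-fold CV, "
            f"have {len(positives)}"
        )
    pos_folds = _partition(positives, n_folds, derive_seed(seed, "folds", 1))
    neg_folds = _partition(negatives, n_folds, derive_seed(seed, "folds", 0))

    collected = {name: [] for name in CLASSIFIER_NAMES}  # (scores, labels) per fold
    fold_sizes = []
    for k in range(n_folds):
        test_pos, test_neg = pos_folds[k], neg_folds[k]
        train_pos = [p for i, f in enumerate(pos_folds) if i != k for p in f]
        train_neg = [p for i, f in enumerate(neg_folds) if i != k for p in f]
        train_pairs = train_pos + train_neg
        train_labels = np.array([1] * len(train_pos) + [0] * len(train_neg))
        test_pairs = test_pos + test_neg
        test_labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
        fold_sizes.append({"fold": k, "test_pos": len(test_pos),
                           "test_neg": len(test_neg)})

        visible = network.with_drug_disease(train_pos) if mask_test_edges else network
        base_scores = []
        for idx, (mp, cm) in enumerate(all_commuting_matrices(visible).items(), 1):
            latent = truncated_svd(cm, latent_feature_percent)
            model = train_base(feature_table(latent, train_pairs), train_labels,
                               derive_seed(seed, mp.value, k), n_trees)
            pos_col = list(model.classes_).index(1)
            s = model.predict_proba(feature_table(latent, test_pairs))[:, pos_col]
            base_scores.append(s)
            collected[f"meta-path-{idx}"].append((s, test_labels))
        collected["ensemble"].append((np.mean(base_scores, axis=0), test_labels))

    pooled, per_fold = {}, {}
    for name in CLASSIFIER_NAMES:
        fold_rows = []
        for k, (s, y) in enumerate(collected[name]):
            aupr_k, auc_k = aupr_auc(s, y)
            fold_rows.append({"fold": k, "AUPR": aupr_k, "AUC": auc_k})
        per_fold[name] = fold_rows
        scores = np.concatenate([s for s, _ in collected[name]])
        labels = np.concatenate([y for _, y in collected[name]])
        aupr, auc = aupr_auc(scores, labels)
        thr = choose_threshold(scores, labels)
        m = metrics(confusion_counts(scores, labels, thr))
        pooled[name] = {"AUPR": aupr, "AUC": auc, "PRE": m.PRE, "REC": m.REC,
                        "ACC": m.ACC, "MCC": m.MCC, "F1": m.F1, "threshold": thr}

    config = {"latent_feature_percent": latent_feature_percent,
              "strategy": strategy, "seed": int(seed), "n_folds": n_folds,
              "n_trees": n_trees, "mask_test_edges": mask_test_edges,
              "n_positives": len(positives)}
    return EvalReport(pooled=pooled, per_fold=per_fold, fold_sizes=fold_sizes,
                      config=config)


def sweep_latent_percent(
    network: HeteroNetwork,
    percents,
    strategy: str = "reliable",
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = DEFAULT_N_TREES,
    mask_test_edges: bool = True,
) -> pd.DataFrame:
    """AUPR/AUC of every classifier across a grid of latent_feature_percent.

    Folds and sampled negatives are fixed across the grid (they depend only
    on the seed), so rows differ in the feature rank alone.
    """
    rows = []
    for pct in percents:
        report = cross_validate(network, latent_feature_percent=pct,
                                strategy=strategy, seed=seed, n_folds=n_folds,
                                n_trees=n_trees, mask_test_edges=mask_test_edges)
        for name in CLASSIFIER_NAMES:
            rows.append({"latent_feature_percent": pct, "classifier": name,
                         "AUPR": report.pooled[name]["AUPR"],
                         "AUC": report.pooled[name]["AUC"]})
    return pd.DataFrame(rows)
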