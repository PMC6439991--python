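"""Per-meta-path random-forest classifiers and their score-averaging ensemble.

Each meta path yields its own feature space (SVD of its commuting matrix)
and its own 256-tree random forest h_i.  The ensemble score of a pair x is
the unweighted mean

    H(x) = (1/5) * sum_i h_i(x)

of the five positive-class probabilities.  A pair is called positive when
H(x) exceeds a threshold chosen to maximise the F1 measure on a reference
score set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._seeds import derive_seed
from .features import LatentFeatures, feature_table, truncated_svd
from .metapaths import MetaPath, all_commuting_matrices
from .network import HeteroNetwork
from .negatives import balanced_training_pairs

DEFAULT_N_TREES = 256


@dataclass
class BaseClassifier:
    """One meta path's fitted random forest."""

    metapath: MetaPath
    model: RandomForestClassifier
    seed: int

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Positive-class probability (fraction of trees voting positive)."""
        proba = self.model.predict_proba(np.atleast_2d(features))
        return proba[:, list(self.model.classes_).index(1)]


def train_base(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
) -> RandomForestClassifier:
    """Fit one random forest; deterministic given the seed."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("cannot train a discriminator on single-class labels")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed),
                                   n_jobs=1)
    model.fit(features, labels)
    return model


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cut maximising F1 of the rule ``score > threshold``.

    Candidates are the midpoints of adjacent sorted unique scores plus one
    value below the minimum (predict everything positive) and one above the
    maximum; ties in F1 go to the smallest threshold.  When all scores are
    identical only the below-minimum cut is usable, so it is returned with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or not scores.size:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    uniq = np.unique(scores)
    below, above = uniq[0] - 1.0, uniq[-1] + 1.0
    if uniq.size == 1:
        warnings.warn("all scores identical; threshold set below the minimum",
                      stacklevel=2)
        return float(below)
    candidates = np.concatenate([[below], (uniq[:-1] + uniq[1:]) / 2.0, [above]])
    n_pos = int(labels.sum())
    best_thr, best_f1 = float(below), -1.0
    for thr in candidates:
        pred = scores > thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = n_pos - tp
        if 2 * tp + fp + fn == 0:
            continue  # no positives predicted or present: F1 undefined
        f1 = 2 * tp / (2 * tp + fp + fn)
        if f1 > best_f1:  # strict: ties keep the smallest threshold
            best_thr, best_f1 = float(thr), f1
    return best_thr


class NotTrainedError(RuntimeError):
    """The ensemble has not been fitted yet."""


@dataclass
class EnsembleModel:
    """Five fitted base classifiers plus their latent feature spaces.

    ``classifiers`` and ``latents`` are keyed by :class:`MetaPath`;
    ``threshold`` is the F1-maximising decision cut (may be ``None`` until
    chosen).  Registries are carried so ranked predictions can be reported
    by entity id.
    """

    classifiers: dict
    latents: dict
    drug_ids: list[str]
    disease_ids: list[str]
    threshold: float | None = None
    latent_feature_percent: float = 0.03

    def __post_init__(self) -> None:
        if set(self.classifiers) != set(MetaPath) or set(self.latents) != set(MetaPath):
            raise ValueError("ensemble requires exactly one classifier and one "
                             "latent feature space per meta path")

    def base_scores(self, pairs) -> dict:
        """Per-meta-path positive-class scores for (drug, disease) index pairs."""
        pairs = list(pairs)
        return {
            mp: self.classifiers[mp].scores(feature_table(self.latents[mp], pairs))
            for mp in MetaPath
        }

    def score_pairs(self, pairs) -> np.ndarray:
        """Ensemble scores H(x) -- the mean of the five base scores."""
        pairs = list(pairs)
        if not pairs:
            return np.empty(0)
        per_path = self.base_scores(pairs)
        return np.mean([per_path[mp] for mp in MetaPath], axis=0)

    def ensemble_score(self, pair) -> float:
        return float(self.score_pairs([pair])[0])

    def predict(self, pairs) -> np.ndarray:
        if self.threshold is None:
            raise NotTrainedError("no decision threshold has been chosen")
        return (self.score_pairs(pairs) > self.threshold).astype(int)

    def rank_candidates(self, network: HeteroNetwork, top_n: int):
        """Highest-scoring unlabeled pairs, as (drug id, disease id, score).

        Scores all pairs without a known treat edge and returns the top
        ``top_n`` in descending score order; exact score ties break by
        (drug id, disease id) lexicographic order.
        """
        if top_n <= 0:
            raise ValueError("top_n must be positive")
        if network.drugs != self.drug_ids or network.diseases != self.disease_ids:
            raise ValueError("network registries do not match the trained model")
        unlabeled = sorted(
            (int(i), int(j))
            for i, j in zip(*np.nonzero(network.a_ds.values.toarray() == 0))
        )
        scores = self.score_pairs(unlabeled)
        # stable sort on descending score; input order is already (drug, disease)
        order = np.argsort(-scores, kind="stable")[:top_n]
        return [
            (self.drug_ids[unlabeled[k][0]], self.disease_ids[unlabeled[k][1]],
             float(scores[k]))
            for k in order
        ]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "EnsembleModel":
        model = joblib.load(path)
        if not isinstance(model, EnsembleModel):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def train_ensemble(
    network: HeteroNetwork,
    latent_feature_percent: float = 0.03,
    strategy: str = "reliable",
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> EnsembleModel:
    """Fit the full five-classifier ensemble on all known associations.

    Uses the network's positives plus an equal-sized seeded draw of
    negatives under ``strategy``; the decision threshold is the
    F1-maximising cut on the training scores (for honest generalisation
    estimates use cross-validation instead).
    """
    labeled = balanced_training_pairs(network, strategy, derive_seed(seed, "negatives"))
    pairs = sorted(labeled.positives) + sorted(labeled.negatives)
    labels = np.array([1] * len(labeled.positives) + [0] * len(labeled.negatives))

    classifiers, latents = {}, {}
    for mp, cm in all_commuting_matrices(network).items():
        latent = truncated_svd(cm, latent_feature_percent)
        clf_seed = derive_seed(seed, mp.value)
        model = train_base(feature_table(latent, pairs), labels, clf_seed, n_trees)
        classifiers[mp] = BaseClassifier(metapath=mp, model=model, seed=clf_seed)
        latents[mp] = latent

    ensemble = EnsembleModel(classifiers=classifiers, latents=latents,
                             drug_ids=list(network.drugs),
                             disease_ids=list(network.diseases),
                             latent_feature_percent=latent_feature_percent)
    ensemble.threshold = choose_threshold(ensemble.score_pairs(pairs), labels)
    return ensemble
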