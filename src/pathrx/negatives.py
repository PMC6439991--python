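"""Selection of likely-negative drug-disease pairs.

Verified treat associations provide positives, but no database records
verified non-associations, so training negatives must come from the
unlabeled pairs.  Picking them uniformly risks mislabeling genuinely
associated pairs that simply have not been confirmed yet.  The reliable
strategy instead keeps only unlabeled pairs whose drug-bound proteins and
disease-associated proteins are disjoint: with no molecular intermediary,
the pair is less plausible as a missed association.

Both strategies (reliable filtering and the uniform-random baseline) are
provided so they can be compared under cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import HeteroNetwork

Pair = tuple[int, int]  # (drug index, disease index)


@dataclass(frozen=True)
class LabeledPairSet:
    """Positive and negative training pairs with the negatives' provenance."""

    positives: frozenset
    negatives: frozenset
    provenance: str = field(default="reliable")  # "reliable" | "random"

    def __post_init__(self) -> None:
        if self.provenance not in ("reliable", "random"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")


def _pair_masks(network: HeteroNetwork) -> tuple[np.ndarray, np.ndarray]:
    """(is_positive, shares_protein) boolean drug x disease grids."""
    pos = network.a_ds.values.toarray().astype(bool)
    overlap = (network.a_dp.values.astype(np.int64)
               @ network.a_sp.values.astype(np.int64).T).toarray() > 0
    return pos, overlap


def reliable_negatives(network: HeteroNetwork) -> set:
    """All unlabeled pairs whose drug and disease share no protein.

    A pair (d, s) qualifies iff the treat layer has no edge for it and the
    dot product of d's drug-protein row with s's disease-protein row is
    zero.  When either protein layer is empty this legitimately returns
    every unlabeled pair.
    """
    pos, overlap = _pair_masks(network)
    keep = ~pos & ~overlap
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(keep))}


def unlabeled_pairs(network: HeteroNetwork) -> set:
    """All pairs without a known treat association."""
    pos = network.a_ds.values.toarray().astype(bool)
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(~pos))}


def sample_negatives(candidates, n: int, seed: int) -> set:
    """Uniform sample of ``n`` pairs without replacement, seeded.

    Candidates are sorted before sampling so the draw depends only on the
    candidate *set* and the seed, not on set iteration order.
    """
    ordered = sorted(candidates)
    if n > len(ordered):
        raise ValueError(
            f"requested {n} negatives but only {len(ordered)} candidates "
            f"are available (short by {n - len(ordered)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return {ordered[k] for k in idx}


def random_unlabeled_negatives(network: HeteroNetwork, n: int, seed: int) -> set:
    """Baseline strategy: sample negatives uniformly from all unlabeled pairs."""
    cands = unlabeled_pairs(network)
    if not cands:
        raise ValueError("no unlabeled pairs: every drug-disease pair is positive")
    return sample_negatives(cands, n, seed)


def negative_candidates(network: HeteroNetwork, strategy: str) -> set:
    """Candidate negative pairs under ``strategy`` ('reliable' or 'random')."""
    if strategy == "reliable":
        return reliable_negatives(network)
    if strategy == "random":
        return unlabeled_pairs(network)
    raise ValueError(f"unknown negative strategy {strategy!r}")


def balanced_training_pairs(network: HeteroNetwork, strategy: str, seed: int) -> LabeledPairSet:
    """Known positives plus an equally sized seeded draw of negatives."""
    positives = frozenset(network.positives())
    cands = negative_candidates(network, strategy)
    negatives = frozenset(sample_negatives(cands, len(positives), seed))
    return LabeledPairSet(positives=positives, negatives=negatives,
                          provenance=strategy)
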