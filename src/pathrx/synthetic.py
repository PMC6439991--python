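"""Synthetic heterogeneous networks with planted treat-association signal.

The generator emulates the statistical structure the predictor relies on:
sparse Bernoulli drug-protein and disease-protein layers, and a drug-disease
treat layer whose edges are enriched among pairs that share interacting
proteins.  The shared-protein enrichment is the planted signal -- it is both
what the protein-mediated meta paths are meant to pick up and what makes the
"no common protein" negative filter informative -- so one fixture exercises
the whole pipeline.

Generation is a pure function of the config (including the seed): identical
configs reproduce identical networks bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .network import HeteroNetwork, InteractionMatrix

PairSet = frozenset  # of (drug_id, disease_id) string tuples


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-signal network generator.

    ``base_treat_rate`` is the treat probability for a drug-disease pair
    sharing no protein; each shared protein adds ``overlap_boost`` to the
    log-odds.  Defaults give a fixture of a few hundred nodes whose layer
    densities (~2%) put a handful of interactions on each node, and a treat
    layer of a few hundred positives, roughly 40% of which are
    protein-mediated.
    """

    n_drugs: int = 200
    n_proteins: int = 150
    n_diseases: int = 80
    density_dp: float = 0.02
    density_sp: float = 0.02
    base_treat_rate: float = 0.01
    overlap_boost: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_proteins", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("density_dp", "density_sp", "base_treat_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.overlap_boost < 0:
            raise ValueError("overlap_boost must be >= 0")


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_network(config: SyntheticConfig) -> tuple[HeteroNetwork, PairSet]:
    """Sample a network and return it with its ground-truth positive pairs.

    The drug-protein and disease-protein layers are independent Bernoulli
    layers at the target densities.  A pair (d, s) becomes a treat edge with
    probability ``logistic(logit(base_treat_rate) + overlap_boost * k)``
    where ``k`` is the number of proteins interacting with both d and s.
    The returned pair set holds the sampled positives as id tuples (the
    treat layer encodes exactly the same set).
    """
    rng = np.random.default_rng(config.seed)
    drugs = _ids("d", config.n_drugs)
    proteins = _ids("p", config.n_proteins)
    diseases = _ids("s", config.n_diseases)

    dp = rng.random((config.n_drugs, config.n_proteins)) < config.density_dp
    spm = rng.random((config.n_diseases, config.n_proteins)) < config.density_sp

    overlap = dp.astype(np.int64) @ spm.astype(np.int64).T  # shared-protein counts
    if config.base_treat_rate == 0.0:
        p = np.zeros_like(overlap, dtype=float)
    elif config.base_treat_rate == 1.0:
        p = np.ones_like(overlap, dtype=float)
    else:
        p = expit(logit(config.base_treat_rate) + config.overlap_boost * overlap)
    ds = rng.random(p.shape) < p
    if not ds.any():
        warnings.warn("synthetic network has no positive treat pairs under "
                      "this configuration", stacklevel=2)

    def layer(mask, row_ids, col_ids, row_type, col_type):
        r, c = np.nonzero(mask)
        edges = [(row_ids[i], col_ids[j]) for i, j in zip(r, c)]
        return InteractionMatrix.from_edges(edges, row_type=row_type,
                                            col_type=col_type,
                                            row_ids=row_ids, col_ids=col_ids)

    network = HeteroNetwork(
        a_dp=layer(dp, drugs, proteins, "Drug", "Protein"),
        a_sp=layer(spm, diseases, proteins, "Disease", "Protein"),
        a_ds=layer(ds, drugs, diseases, "Drug", "Disease"),
        drugs=drugs, proteins=proteins, diseases=diseases,
    )
    positives = frozenset(
        (drugs[i], diseases[j]) for i, j in zip(*np.nonzero(ds))
    )
    return network, positives


def hide_positives(
    network: HeteroNetwork,
    fraction: float,
    seed: int,
) -> tuple[HeteroNetwork, PairSet]:
    """Remove a random fraction of treat edges from the network.

    Returns the reduced network and the hidden pairs (as id tuples).  Used
    to study recovery of unobserved associations: the hidden positives look
    unlabeled to the pipeline but are known to the experimenter.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    positives = network.positives()
    rng = np.random.default_rng(seed)
    n_hide = int(round(fraction * len(positives)))
    hidden_idx = rng.choice(len(positives), size=n_hide, replace=False)
    hidden = {positives[k] for k in hidden_idx}
    kept = [p for p in positives if p not in hidden]
    reduced = network.with_drug_disease(kept)
    hidden_ids = frozenset(
        (network.drugs[i], network.diseases[j]) for i, j in hidden
    )
    return reduced, hidden_ids


def write_network(network: HeteroNetwork, out_dir, positives: PairSet | None = None) -> dict[str, str]:
    """Write the three TSV edge lists (and optional ground truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in (("drug_protein", network.a_dp),
                      ("disease_protein", network.a_sp),
                      ("drug_disease", network.a_ds)):
        p = out / f"{name}.tsv"
        mat.write_edge_list(p)
        paths[name] = str(p)
    if positives is not None:
        p = out / "ground_truth_positives.tsv"
        lines = [f"{d}\t{s}" for d, s in sorted(positives)]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths["ground_truth_positives"] = str(p)
    return paths


def config_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
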