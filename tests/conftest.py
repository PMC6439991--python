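"""Shared fixtures: toy worked-example network, random small networks,
synthetic planted-signal networks and (expensive, session-scoped)
cross-validation replicates."""

from __future__ import annotations

import numpy as np
import pytest

import pathrx as px


def make_toy_network():
    """The worked path-counting example: drug d3 binds proteins p3 and p5,
    both of which cause disease s2, so there are exactly two drug->protein->
    disease path instances from d3 to s2."""
    a_dp = px.InteractionMatrix.from_edges(
        [("d1", "p1"), ("d2", "p2"), ("d3", "p3"), ("d3", "p5"), ("d2", "p4")],
        row_type="Drug", col_type="Protein",
    )
    a_sp = px.InteractionMatrix.from_edges(
        [("s1", "p1"), ("s1", "p2"), ("s2", "p3"), ("s2", "p5")],
        row_type="Disease", col_type="Protein",
    )
    a_ds = px.InteractionMatrix.from_edges(
        [("d1", "s1")], row_type="Drug", col_type="Disease",
    )
    return px.build_network(a_dp, a_sp, a_ds)


@pytest.fixture
def toy_network():
    return make_toy_network()


def random_network(rng, n_drugs=None, n_proteins=None, n_diseases=None,
                   p_edge=0.3):
    """A small random heterogeneous network (direct construction, not the
    planted-signal generator), for oracle comparisons."""
    n_drugs = n_drugs or int(rng.integers(2, 8))
    n_proteins = n_proteins or int(rng.integers(2, 7))
    n_diseases = n_diseases or int(rng.integers(2, 6))
    drugs = [f"d{i}" for i in range(n_drugs)]
    proteins = [f"p{i}" for i in range(n_proteins)]
    diseases = [f"s{i}" for i in range(n_diseases)]

    def layer(rows, cols, row_type, col_type):
        mask = rng.random((len(rows), len(cols))) < p_edge
        edges = [(rows[i], cols[j]) for i, j in zip(*np.nonzero(mask))]
        return px.InteractionMatrix.from_edges(
            edges, row_type=row_type, col_type=col_type,
            row_ids=rows, col_ids=cols,
        )

    return px.HeteroNetwork(
        a_dp=layer(drugs, proteins, "Drug", "Protein"),
        a_sp=layer(diseases, proteins, "Disease", "Protein"),
        a_ds=layer(drugs, diseases, "Drug", "Disease"),
        drugs=drugs, proteins=proteins, diseases=diseases,
    )


@pytest.fixture
def planted_network():
    """Default planted-signal synthetic network, fixed seed."""
    network, positives = px.generate_network(px.SyntheticConfig(seed=11))
    return network, positives


@pytest.fixture(scope="session")
def cv_replicates():
    """Cross-validation reports over 20 generator/pipeline seeds.

    Computed once per session (the costly part of the suite) and shared by
    the signal-recovery and ensemble-dominance checks.  The protocol
    rebuilds features from the full treat layer (mask_test_edges=False),
    matching the original benchmark protocol in which commuting matrices
    are computed once from all known associations.
    """
    reports = []
    for seed in range(20):
        network, _ = px.generate_network(px.SyntheticConfig(seed=seed))
        reports.append(px.cross_validate(network, seed=seed,
                                         mask_test_edges=False))
    return reports
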