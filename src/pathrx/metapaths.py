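"""Meta paths over the drug-protein-disease schema and their commuting matrices.

A meta path is a typed node/link template such as
Drug --binds to--> Protein --causes--> Disease.  Its commuting matrix is the
product of the interaction matrices along the template; entry (i, j) counts
the path instances (walks -- intermediate nodes may repeat) from drug i to
disease j.  Five drug-to-disease meta paths of length at most three are
used; longer templates add little and are deliberately excluded.

With A_dp (drug x protein), A_sp (disease x protein) and A_ds
(drug x disease):

    MP1:  Drug -> Disease                       X1 = A_ds
    MP2:  Drug -> Protein -> Disease            X2 = A_dp . A_sp^T
    MP3:  Drug -> Protein -> Drug -> Disease    X3 = A_dp . A_dp^T . A_ds
    MP4:  Drug -> Disease -> Drug -> Disease    X4 = A_ds . A_ds^T . A_ds
    MP5:  Drug -> Disease -> Protein -> Disease X5 = A_ds . A_sp . A_sp^T

Besides the matrix products, :func:`count_path_instances` enumerates the
walks explicitly; the two routes agree entrywise and the enumeration serves
as the independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.sparse as sp

from .network import HeteroNetwork


class MetaPath(str, Enum):
    """The five drug-to-disease meta paths of length <= 3."""

    MP1 = "MP1"
    MP2 = "MP2"
    MP3 = "MP3"
    MP4 = "MP4"
    MP5 = "MP5"

    @property
    def node_sequence(self) -> tuple[str, ...]:
        return _NODE_SEQUENCES[self]

    @property
    def length(self) -> int:
        """Number of links in the template."""
        return len(self.node_sequence) - 1


_NODE_SEQUENCES = {
    MetaPath.MP1: ("Drug", "Disease"),
    MetaPath.MP2: ("Drug", "Protein", "Disease"),
    MetaPath.MP3: ("Drug", "Protein", "Drug", "Disease"),
    MetaPath.MP4: ("Drug", "Disease", "Drug", "Disease"),
    MetaPath.MP5: ("Drug", "Disease", "Protein", "Disease"),
}

# each step: (layer name, transpose?) -- the factor matrices in product order
_STEPS = {
    MetaPath.MP1: (("ds", False),),
    MetaPath.MP2: (("dp", False), ("sp", True)),
    MetaPath.MP3: (("dp", False), ("dp", True), ("ds", False)),
    MetaPath.MP4: (("ds", False), ("ds", True), ("ds", False)),
    MetaPath.MP5: (("ds", False), ("sp", False), ("sp", True)),
}


@dataclass
class CommutingMatrix:
    """Drug x disease path-instance counts for one meta path."""

    values: sp.csr_array  # nonnegative integers
    metapath: MetaPath
    drug_ids: list[str]
    disease_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self, drug_id: str, disease_id: str) -> int:
        i = self.drug_ids.index(drug_id)
        j = self.disease_ids.index(disease_id)
        return int(self.values[i, j])

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def write_mtx(self, path) -> None:
        """Export as a MatrixMarket file for inspection."""
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_array(self.values))


def _factors(network: HeteroNetwork, metapath: MetaPath) -> list[sp.csr_array]:
    layers = {"dp": network.a_dp.values, "sp": network.a_sp.values,
              "ds": network.a_ds.values}
    mats = []
    for name, transpose in _STEPS[metapath]:
        m = layers[name].astype(np.int64)
        mats.append(sp.csr_array(m.T) if transpose else m)
    return mats


def commuting_matrix(network: HeteroNetwork, metapath: MetaPath) -> CommutingMatrix:
    """Exact integer product of the interaction matrices along ``metapath``.

    Evaluated left-to-right over sparse matrices; the association order
    affects cost only, never the values.
    """
    metapath = MetaPath(metapath)
    mats = _factors(network, metapath)
    product = mats[0]
    for m in mats[1:]:
        product = product @ m
    return CommutingMatrix(values=sp.csr_array(product), metapath=metapath,
                           drug_ids=list(network.drugs),
                           disease_ids=list(network.diseases))


def count_path_instances(
    network: HeteroNetwork,
    metapath: MetaPath,
    drug: int,
    disease: int,
) -> int:
    """Enumerate the walks from ``drug`` to ``disease`` matching ``metapath``.

    Walk semantics: intermediate nodes may repeat (a drug may be revisited),
    matching what the matrix product counts.  Index arguments are 0-based
    positions in the network's drug / disease registries.
    """
    metapath = MetaPath(metapath)
    if not 0 <= drug < network.n_drugs:
        raise IndexError(f"drug index {drug} out of range")
    if not 0 <= disease < network.n_diseases:
        raise IndexError(f"disease index {disease} out of range")
    # adjacency lists per step (csr row slices), cheap to traverse repeatedly
    steps = []
    for m in _factors(network, metapath):
        m = m.tocsr()
        steps.append((m.indptr, m.indices))

    def walk(step: int, node: int) -> int:
        if step == len(steps):
            return 1 if node == disease else 0
        indptr, indices = steps[step]
        return sum(walk(step + 1, int(j))
                   for j in indices[indptr[node]:indptr[node + 1]])

    return walk(0, drug)


def all_commuting_matrices(network: HeteroNetwork) -> dict[MetaPath, CommutingMatrix]:
    """Commuting matrices for all five meta paths."""
    return {mp: commuting_matrix(network, mp) for mp in MetaPath}
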