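"""Heterogeneous drug-protein-disease interaction networks.

The predictor consumes three sparse binary interaction layers: drug-protein
("binds to"), disease-protein ("causes" / "caused by") and drug-disease
("treats").  This module loads the layers from two-column TSV edge lists,
aligns them onto shared identifier registries, and reports the descriptive
statistics (node counts, edge counts, layer densities) customarily used to
summarise such networks.

Identifiers are opaque, case-sensitive strings.  Registries are kept sorted
lexicographically so that matrix indices are stable across runs; all
internal indexing is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

NODE_TYPES = ("Drug", "Protein", "Disease")


class EdgeListParseError(ValueError):
    """A malformed line or empty interaction edge-list file."""


class NetworkConfigError(ValueError):
    """Node-type labels of the three layers are mutually inconsistent."""


def _binary_csr(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> sp.csr_array:
    data = np.ones(len(rows), dtype=np.int8)
    return sp.csr_array(sp.coo_array((data, (rows, cols)), shape=shape))


@dataclass
class InteractionMatrix:
    """Binary adjacency between two node-type universes.

    ``values[i, j] == 1`` iff an interaction between ``row_ids[i]`` and
    ``col_ids[j]`` was observed.  Duplicate input edges collapse to a single
    entry, so ``values.nnz`` equals the number of distinct edges.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: sp.csr_array
    row_type: str
    col_type: str
    row_index: dict[str, int] = field(init=False, repr=False, compare=False)
    col_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.row_type not in NODE_TYPES or self.col_type not in NODE_TYPES:
            raise NetworkConfigError(
                f"node types must be in {NODE_TYPES}, got "
                f"({self.row_type!r}, {self.col_type!r})"
            )
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column identifiers")
        self.values = sp.csr_array(self.values).astype(np.int8)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match registries "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        self.values.eliminate_zeros()
        if self.values.nnz and not np.all(self.values.data == 1):
            raise ValueError("interaction matrix entries must be 0 or 1")
        self.row_index = {r: i for i, r in enumerate(self.row_ids)}
        self.col_index = {c: j for j, c in enumerate(self.col_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nnz(self) -> int:
        return int(self.values.nnz)

    @property
    def density(self) -> float:
        return compute_density(self.nnz, *self.shape)

    @classmethod
    def from_edges(
        cls,
        edges,
        row_type: str,
        col_type: str,
        row_ids: list[str] | None = None,
        col_ids: list[str] | None = None,
    ) -> "InteractionMatrix":
        """Build a matrix from (row_id, col_id) pairs.

        Registries default to the sorted unique identifiers seen in the
        edges; explicit registries may add isolated nodes.
        """
        uniq = sorted({(str(r), str(c)) for r, c in edges})
        if row_ids is None:
            row_ids = sorted({r for r, _ in uniq})
        if col_ids is None:
            col_ids = sorted({c for _, c in uniq})
        ridx = {r: i for i, r in enumerate(row_ids)}
        cidx = {c: j for j, c in enumerate(col_ids)}
        try:
            rows = np.fromiter((ridx[r] for r, _ in uniq), dtype=np.intp, count=len(uniq))
            cols = np.fromiter((cidx[c] for _, c in uniq), dtype=np.intp, count=len(uniq))
        except KeyError as exc:  # an edge references an id outside the registry
            raise ValueError(f"edge references unknown identifier {exc.args[0]!r}") from exc
        values = _binary_csr(rows, cols, (len(row_ids), len(col_ids)))
        return cls(row_ids=row_ids, col_ids=col_ids, values=values,
                   row_type=row_type, col_type=col_type)

    def has_edge(self, row_id: str, col_id: str) -> bool:
        i, j = self.row_index.get(row_id), self.col_index.get(col_id)
        if i is None or j is None:
            return False
        return bool(self.values[i, j])

    def edges(self) -> list[tuple[str, str]]:
        """All (row_id, col_id) interactions, sorted."""
        coo = self.values.tocoo()
        return sorted(
            (self.row_ids[i], self.col_ids[j]) for i, j in zip(coo.row, coo.col)
        )

    def reindex(self, row_ids: list[str], col_ids: list[str]) -> "InteractionMatrix":
        """Re-map the matrix onto larger registries, zero-padding new ids.

        Every id currently present must appear in the target registries.
        """
        ridx = {r: i for i, r in enumerate(row_ids)}
        cidx = {c: j for j, c in enumerate(col_ids)}
        missing = [r for r in self.row_ids if r not in ridx] + \
                  [c for c in self.col_ids if c not in cidx]
        if missing:
            raise ValueError(f"target registries drop identifiers: {missing[:5]}")
        coo = self.values.tocoo()
        rows = np.array([ridx[self.row_ids[i]] for i in coo.row], dtype=np.intp)
        cols = np.array([cidx[self.col_ids[j]] for j in coo.col], dtype=np.intp)
        values = _binary_csr(rows, cols, (len(row_ids), len(col_ids)))
        return InteractionMatrix(row_ids=list(row_ids), col_ids=list(col_ids),
                                 values=values, row_type=self.row_type,
                                 col_type=self.col_type)

    def write_edge_list(self, path) -> None:
        """Write the interactions as a two-column TSV edge list."""
        lines = [f"{r}\t{c}" for r, c in self.edges()]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_interaction_edges(
    path,
    row_type: str,
    col_type: str,
    skip_header: bool = False,
) -> InteractionMatrix:
    """Parse a two-column TSV edge list into a binary interaction matrix.

    Lines beginning with ``#`` and blank lines are ignored.  When
    ``skip_header`` is true the first remaining line is dropped as a column
    header.  Each usable line must carry at least two tab-separated fields
    (row identifier, column identifier); extra fields are ignored.
    Duplicate edges collapse to a single entry.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    header_pending = skip_header
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header_pending:
                header_pending = False
                continue
            fields = [f.strip() for f in line.split("\t")]
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path.name}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}: {line!r}"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        raise EdgeListParseError(f"{path.name}: no interaction edges found")
    return InteractionMatrix.from_edges(edges, row_type=row_type, col_type=col_type)


@dataclass
class HeteroNetwork:
    """The three aligned interaction layers plus shared id registries.

    ``a_dp`` is Drug x Protein, ``a_sp`` is Disease x Protein and ``a_ds``
    is Drug x Disease; their registries are identical object-for-object with
    ``drugs`` / ``proteins`` / ``diseases``.
    """

    a_dp: InteractionMatrix
    a_sp: InteractionMatrix
    a_ds: InteractionMatrix
    drugs: list[str]
    proteins: list[str]
    diseases: list[str]

    def __post_init__(self) -> None:
        if not (self.a_dp.row_ids == self.a_ds.row_ids == self.drugs):
            raise NetworkConfigError("drug registries are not aligned")
        if not (self.a_dp.col_ids == self.a_sp.col_ids == self.proteins):
            raise NetworkConfigError("protein registries are not aligned")
        if not (self.a_sp.row_ids == self.a_ds.col_ids == self.diseases):
            raise NetworkConfigError("disease registries are not aligned")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def positives(self) -> list[tuple[int, int]]:
        """Known treat associations as sorted (drug index, disease index)."""
        coo = self.a_ds.values.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def with_drug_disease(self, pairs) -> "HeteroNetwork":
        """Copy of the network whose treat layer holds exactly ``pairs``.

        ``pairs`` are (drug index, disease index) tuples.  Used to mask
        held-out associations during cross-validation.
        """
        pairs = sorted(set(pairs))
        if pairs:
            rows = np.array([i for i, _ in pairs], dtype=np.intp)
            cols = np.array([j for _, j in pairs], dtype=np.intp)
        else:
            rows = cols = np.array([], dtype=np.intp)
        values = _binary_csr(rows, cols, (self.n_drugs, self.n_diseases))
        a_ds = InteractionMatrix(row_ids=self.drugs, col_ids=self.diseases,
                                 values=values, row_type="Drug", col_type="Disease")
        return HeteroNetwork(a_dp=self.a_dp, a_sp=self.a_sp, a_ds=a_ds,
                             drugs=self.drugs, proteins=self.proteins,
                             diseases=self.diseases)


def build_network(
    a_dp: InteractionMatrix,
    a_sp: InteractionMatrix,
    a_ds: InteractionMatrix,
) -> HeteroNetwork:
    """Align the three layers onto union registries per node type.

    Drugs are the union of the drug-protein rows and drug-disease rows,
    proteins the union of the protein columns, diseases the union of the
    disease-protein rows and drug-disease columns.  Entities absent from a
    layer get all-zero rows/columns, so every layer's edge set is preserved.
    """
    expected = {"a_dp": ("Drug", "Protein"), "a_sp": ("Disease", "Protein"),
                "a_ds": ("Drug", "Disease")}
    for name, mat in (("a_dp", a_dp), ("a_sp", a_sp), ("a_ds", a_ds)):
        if (mat.row_type, mat.col_type) != expected[name]:
            raise NetworkConfigError(
                f"{name} must be {expected[name]}, got "
                f"({mat.row_type!r}, {mat.col_type!r})"
            )
    drugs = sorted(set(a_dp.row_ids) | set(a_ds.row_ids))
    proteins = sorted(set(a_dp.col_ids) | set(a_sp.col_ids))
    diseases = sorted(set(a_sp.row_ids) | set(a_ds.col_ids))
    return HeteroNetwork(
        a_dp=a_dp.reindex(drugs, proteins),
        a_sp=a_sp.reindex(diseases, proteins),
        a_ds=a_ds.reindex(drugs, diseases),
        drugs=drugs, proteins=proteins, diseases=diseases,
    )


def compute_density(n_edges: int, n_rows: int, n_cols: int) -> float:
    """Fraction of realised interactions: ``n_edges / (n_rows * n_cols)``."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("density is undefined for an empty node universe")
    if not 0 <= n_edges <= n_rows * n_cols:
        raise ValueError(f"edge count {n_edges} outside [0, {n_rows * n_cols}]")
    return n_edges / (n_rows * n_cols)


def summarize(network: HeteroNetwork) -> dict:
    """Node counts, interaction counts and densities of the three layers."""
    return {
        "nodes": {
            "drugs": network.n_drugs,
            "proteins": network.n_proteins,
            "diseases": network.n_diseases,
        },
        "interactions": {
            "drug_protein": {"count": network.a_dp.nnz, "density": network.a_dp.density},
            "disease_protein": {"count": network.a_sp.nnz, "density": network.a_sp.density},
            "drug_disease": {"count": network.a_ds.nnz, "density": network.a_ds.density},
        },
    }


def write_summary(network: HeteroNetwork, path) -> None:
    Path(path).write_text(json.dumps(summarize(network), indent=2) + "\n")
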