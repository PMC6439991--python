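"""Latent drug/disease features via truncated SVD of commuting matrices.

A commuting matrix X (m drugs x n diseases) is factorised as
X = U S V^T and truncated to its top r singular triplets, where the rank is
controlled by a single fraction:

    r = max(1, floor(latent_feature_percent * min(m, n)))

Row i of U_r is the latent feature vector of drug i, row j of V_r that of
disease j, and a drug-disease pair is represented by their concatenation
(length 2r).  Rows are used as-is, without weighting by the singular
values.  The sign ambiguity of singular vectors is resolved by forcing the
largest-magnitude entry of each left singular vector to be positive, which
makes the features bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .metapaths import CommutingMatrix, MetaPath

# below this size a dense LAPACK SVD is cheaper and fully deterministic
_DENSE_LIMIT = 2000


def retained_rank(latent_feature_percent: float, m: int, n: int) -> int:
    """Rank kept by the truncation rule; at least 1, at most min(m, n)."""
    if not 0.0 < latent_feature_percent < 1.0:
        raise ValueError("latent_feature_percent must lie in (0, 1)")
    return max(1, int(np.floor(latent_feature_percent * min(m, n))))


@dataclass
class LatentFeatures:
    """Top-r singular triplet of one meta path's commuting matrix."""

    U: np.ndarray  # m x r, left singular vectors
    S: np.ndarray  # r singular values, non-increasing
    V: np.ndarray  # n x r, right singular vectors
    r: int
    latent_feature_percent: float
    metapath: MetaPath

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def reconstruction(self) -> np.ndarray:
        """The best rank-r approximation U_r diag(S_r) V_r^T."""
        return (self.U * self.S) @ self.V.T

    def singular_value_coverage(self) -> float:
        """Diagnostic: retained sum of singular values over the total sum.

        Requires recomputing the full spectrum, so intended for small
        matrices / reporting only.
        """
        full = np.linalg.svd(self.reconstruction(), compute_uv=False)
        total = full.sum()
        return float(self.S.sum() / total) if total else float("nan")


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip each (u_k, v_k) so the largest-|.| entry of u_k is positive;
    # argmax takes the first maximiser, so ties break deterministically
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, V


def truncated_svd(X: CommutingMatrix, latent_feature_percent: float) -> LatentFeatures:
    """Top-r singular triplet of a commuting matrix.

    Uses a dense LAPACK SVD when min(m, n) is small (always exact and
    deterministic) and ARPACK with a fixed starting vector for large sparse
    matrices.  Raises on an all-zero matrix: such a meta path carries no
    information on the given network and cannot contribute features.
    """
    m, n = X.shape
    r = retained_rank(latent_feature_percent, m, n)
    A = X.values.astype(np.float64)
    if A.nnz == 0:
        raise ValueError(
            f"commuting matrix for {X.metapath.value} is identically zero: "
            "this meta path carries no information on this network"
        )
    if min(m, n) <= _DENSE_LIMIT or r >= min(m, n) - 1:
        U, S, Vt = np.linalg.svd(A.toarray(), full_matrices=False)
        U, S, V = U[:, :r], S[:r], Vt[:r].T
    else:
        v0 = np.full(min(m, n), 1.0 / np.sqrt(min(m, n)))
        U, S, Vt = spla.svds(sp.csr_matrix(A), k=r, v0=v0)
        order = np.argsort(S)[::-1]  # svds returns ascending
        U, S, V = U[:, order], S[order], Vt[order].T
    U, V = _fix_signs(np.ascontiguousarray(U), np.ascontiguousarray(V))
    return LatentFeatures(U=U, S=np.asarray(S), V=V, r=r,
                          latent_feature_percent=latent_feature_percent,
                          metapath=X.metapath)


def pair_feature_vector(latent: LatentFeatures, drug: int, disease: int) -> np.ndarray:
    """Feature vector of one pair: [U_r row drug || V_r row disease]."""
    if not 0 <= drug < latent.m:
        raise IndexError(f"drug index {drug} out of range [0, {latent.m})")
    if not 0 <= disease < latent.n:
        raise IndexError(f"disease index {disease} out of range [0, {latent.n})")
    return np.concatenate([latent.U[drug], latent.V[disease]])


def feature_table(latent: LatentFeatures, pairs) -> np.ndarray:
    """Stacked pair feature vectors, one row per (drug, disease) pair."""
    pairs = list(pairs)
    if not pairs:
        return np.empty((0, 2 * latent.r))
    drugs = np.asarray([p[0] for p in pairs])
    diseases = np.asarray([p[1] for p in pairs])
    if drugs.min() < 0 or drugs.max() >= latent.m:
        raise IndexError("drug index out of range")
    if diseases.min() < 0 or diseases.max() >= latent.n:
        raise IndexError("disease index out of range")
    return np.hstack([latent.U[drugs], latent.V[diseases]])
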