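"""Recursive multi-kernel integration of relevance-ordered synergy views.

The accretive basis starts as the eigenbasis of the most relevant view.  Each
remaining view's eigenbasis is projected onto the accretive subspace, the
residual is Gram-Schmidt orthogonalised, row-normalised, and attenuated by a
sign-preserving elementwise power that grows with the recursion step, so less
relevant views perturb the basis less.  k-means on the rows of the final
basis yields the sample labels.

Only the n x k basis is ever carried: the full n x n accretive matrix that
the recursion nominally updates is never needed downstream, and the basis
update is mathematically equivalent for everything that is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._random import substream_seed
from .synergy import SynergyView

__all__ = [
    "AccretiveBasis",
    "ClusteringResult",
    "project_basis",
    "residual",
    "gram_schmidt",
    "orthonorm_weight",
    "integrate",
    "cluster_accretive",
]


@dataclass
class AccretiveBasis:
    """The n x k basis carried through the recursion, and the step index."""

    b: np.ndarray
    step: int = 1


@dataclass
class ClusteringResult:
    """Final labels plus the integrated basis and per-view diagnostics."""

    labels: np.ndarray
    b_final: np.ndarray
    per_view: list[dict] = field(default_factory=list)
    k: int = 0
    seed: int = 0
    empty_clusters: bool = False


def project_basis(b: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Projection of U onto the accretive subspace: ``b b^T U``."""
    b = np.asarray(b, dtype=float)
    U = np.asarray(U, dtype=float)
    if b.shape != U.shape:
        raise ValueError(f"shape mismatch: b {b.shape} vs U {U.shape}")
    return b @ (b.T @ U)


def residual(U: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Residual component ``U - P`` of the view eigenspace."""
    U = np.asarray(U, dtype=float)
    P = np.asarray(P, dtype=float)
    if U.shape != P.shape:
        raise ValueError(f"shape mismatch: U {U.shape} vs P {P.shape}")
    return U - P


def gram_schmidt(Q: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Modified Gram-Schmidt orthonormalisation, keeping the column count.

    Columns whose residual norm falls below ``tol`` (numerically dependent
    columns) are replaced by zero columns, so the output has the same shape
    as the input, with the nonzero columns orthonormal.
    """
    Q = np.asarray(Q, dtype=float).copy()
    n, k = Q.shape
    for j in range(k):
        v = Q[:, j]
        for i in range(j):
            u = Q[:, i]
            # zero columns contribute nothing
            v = v - (u @ v) * u
        norm = np.linalg.norm(v)
        Q[:, j] = v / norm if norm >= tol else 0.0
    return Q


def orthonorm_weight(R: np.ndarray, eta: int) -> np.ndarray:
    """Row-normalise R, then attenuate entries by a sign-preserving power.

    Each nonzero row is divided by its Euclidean norm; each entry x is then
    mapped to ``sign(x) * |x|**(eta + 1)``.  Unit rows have entries with
    magnitude <= 1, so larger eta shrinks each entry: views merged later
    (less relevant ones) contribute less per entry.

    Note that :func:`integrate` by default applies the attenuating power to
    the orthonormalised residual *without* the per-row rescaling: rescaling
    every row to unit length inflates the contribution of a view to
    Frobenius norm ~ sqrt(n), roughly sqrt(n/k) times the scale of the
    orthonormal accretive basis it is added to, which lets the least
    relevant view dominate the basis instead of perturbing it.  The fully
    row-rescaled form stays available via ``integrate(...,
    row_normalize=True)``.
    """
    return _orthonorm_weight(R, eta, sign_preserving=True, row_normalize=True)


def _orthonorm_weight(
    R: np.ndarray, eta: int, sign_preserving: bool, row_normalize: bool
) -> np.ndarray:
    if eta < 0:
        raise ValueError("eta must be >= 0")
    V = np.asarray(R, dtype=float)
    if row_normalize:
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        V = np.where(norms > 0, V / np.where(norms > 0, norms, 1.0), 0.0)
    p = eta + 1
    if sign_preserving:
        return np.sign(V) * np.abs(V) ** p
    return V**p


def integrate(
    svs: list[SynergyView],
    k: int,
    literal_power: bool = False,
    reorthonormalize: bool = False,
    row_normalize: bool = False,
) -> AccretiveBasis:
    """Merge relevance-ordered views into the final accretive basis.

    The recursion runs M - 1 times: at step eta (merging view eta + 1) the
    weighted residual of that view's eigenbasis is added to the basis.  The
    attenuating power is applied to the orthonormalised residual directly
    (entries already bounded by 1); ``row_normalize=True`` first rescales
    every residual row to unit length, which puts each merged view on a
    much larger scale than the basis (see :func:`orthonorm_weight`).
    ``reorthonormalize`` re-orthonormalises the summed basis between steps
    (off by default: the plain sum is the documented behaviour).
    """
    if not svs:
        raise ValueError("need at least one synergy view")
    n = svs[0].U_k.shape[0]
    for sv in svs:
        if sv.U_k.shape != (n, k):
            raise ValueError(
                f"view {sv.name!r}: eigenbasis shape {sv.U_k.shape} != ({n}, {k})"
            )
    b = svs[0].U_k.copy()
    for eta, sv in enumerate(svs[1:], start=1):
        # project onto span(b): once merges have been added, b is no longer
        # orthonormal, so the projection uses an orthonormalised copy (at
        # step 1 this is b b^T U exactly); the residual is then orthogonal
        # to the accretive subspace at every step, not just the first
        b_orth = gram_schmidt(b)
        P = project_basis(b_orth, sv.U_k)
        Q = residual(sv.U_k, P)
        R = gram_schmidt(Q)
        V = _orthonorm_weight(
            R, eta, sign_preserving=not literal_power, row_normalize=row_normalize
        )
        b = b + V
        if reorthonormalize:
            b = gram_schmidt(b)
    return AccretiveBasis(b=b, step=len(svs))


def cluster_accretive(
    b: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    t_max: int = 300,
) -> np.ndarray:
    """k-means on the rows of the accretive basis.

    Labels are canonicalised by order of first occurrence, so the same
    partition always gets the same label vector.
    """
    b = np.asarray(b, dtype=float)
    n = b.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=t_max,
        random_state=substream_seed(seed, "final_kmeans"),
    ).fit(b)
    return canonicalize_labels(km.labels_)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first occurrence (0, 1, 2, ...)."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping)
        out[i] = mapping[key]
    return out
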