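"""Per-view graph representations.

Every view is turned into two sample-similarity representations that feed the
synergy step:

* the Gramian ``G``: a heat kernel over pairwise *correlation* distances,
  ``G_ij = exp(-phi_ij / phi_max)``.  Two samples are similar when the trends
  across their features correlate, regardless of scale.
* the shifted normalised Laplacian ``L``: the similarity matrix ``W`` is the
  same heat kernel over pairwise *squared Euclidean* distances; from it the
  degree vector ``d``, the normalised Laplacian
  ``Lnorm = I - D^{-1/2} W D^{-1/2}`` and the shift
  ``L = Lnorm + (2/n) 1 1^T`` are assembled.  The shift moves the trivial
  constant eigenvector away from the bottom of the spectrum (exactly so on
  regular graphs) so the informative eigenvectors can be taken directly.

Both kernels divide by the maximum observed distance, so entries lie in
``(0, 1]`` with a unit diagonal and both matrices are PSD up to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OmicsView

__all__ = [
    "DistanceMatrix",
    "RepresentationPair",
    "pairwise_distances",
    "heat_kernel",
    "degree_matrix",
    "normalized_laplacian",
    "shift_laplacian",
    "build_representations",
]

METRICS = ("correlation", "squared_euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise sample distances and their maximum."""

    Dmat: np.ndarray
    metric: str
    max_value: float


@dataclass
class RepresentationPair:
    """The matrices derived from one view: W, degree d, G, Lnorm, L."""

    name: str
    W: np.ndarray
    d: np.ndarray
    G: np.ndarray
    Lnorm: np.ndarray
    Lmod: np.ndarray


def pairwise_distances(X: np.ndarray, metric: str) -> DistanceMatrix:
    """Pairwise distances between the columns (samples) of ``X``.

    ``correlation`` is 1 - Pearson correlation (range [0, 2]);
    ``squared_euclidean`` is the squared L2 distance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be a d x n matrix with n >= 2 samples")
    if metric == "correlation":
        sd = X.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance sample at column index {bad[0]} under "
                "correlation distance"
            )
        D = 1.0 - np.corrcoef(X, rowvar=False)
    elif metric == "squared_euclidean":
        sq = np.einsum("ij,ij->j", X, X)
        D = sq[:, None] + sq[None, :] - 2.0 * (X.T @ X)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    D = np.maximum(0.5 * (D + D.T), 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(Dmat=D, metric=metric, max_value=float(D.max()))


def heat_kernel(
    dist: DistanceMatrix,
    scale_factor: float = 1.0,
    squared: bool = False,
) -> np.ndarray:
    """Similarity ``exp(-D_ij / (scale_factor * max(D)))``.

    ``scale_factor=1`` divides by the maximum pairwise distance itself;
    ``scale_factor=0.5`` uses half the maximum instead.  ``squared`` applies
    the exponential factor twice, ``exp(-2 D / max)``.  All points identical
    (zero maximum) degenerates to the all-ones matrix.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    n = dist.Dmat.shape[0]
    if dist.max_value == 0.0:
        return np.ones((n, n))
    expo = 2.0 if squared else 1.0
    K = np.exp(-expo * dist.Dmat / (scale_factor * dist.max_value))
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def degree_matrix(W: np.ndarray) -> np.ndarray:
    """Degree of each node: row sums of W (diagonal included)."""
    W = np.asarray(W, dtype=float)
    return W.sum(axis=1)


def normalized_laplacian(W: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Symmetric normalised Laplacian ``I - D^{-1/2} W D^{-1/2}``."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("all degrees must be strictly positive")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    L[np.diag_indices_from(L)] += 1.0
    return 0.5 * (L + L.T)


def shift_laplacian(Lnorm: np.ndarray, n: int | None = None) -> np.ndarray:
    """Add the rank-one shift ``(2/n) 1 1^T`` to the normalised Laplacian.

    Eigenvectors orthogonal to the constant vector keep their eigenpairs; on a
    regular graph the constant eigenvector moves from eigenvalue 0 to 2.
    """
    Lnorm = np.asarray(Lnorm, dtype=float)
    if n is None:
        n = Lnorm.shape[0]
    return Lnorm + 2.0 / n


def build_representations(
    view: OmicsView,
    scale_factor: float = 1.0,
    gramian_squared: bool = False,
    zero_diagonal: bool = False,
) -> RepresentationPair:
    """Assemble G, W, d, Lnorm and the shifted Laplacian for one view.

    ``zero_diagonal`` removes self-loops from W before the degree and
    Laplacian computations.
    """
    G = heat_kernel(
        pairwise_distances(view.X, "correlation"),
        scale_factor=scale_factor,
        squared=gramian_squared,
    )
    W = heat_kernel(
        pairwise_distances(view.X, "squared_euclidean"), scale_factor=scale_factor
    )
    if zero_diagonal:
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    d = degree_matrix(W)
    Lnorm = normalized_laplacian(W, d)
    Lmod = shift_laplacian(Lnorm)
    return RepresentationPair(name=view.name, W=W, d=d, G=G, Lnorm=Lnorm, Lmod=Lmod)


def min_relative_eigenvalue(A: np.ndarray) -> float:
    """Smallest eigenvalue of a symmetric matrix, scaled by the largest
    eigenvalue magnitude; a PSD matrix gives a value >= -tol."""
    vals = np.linalg.eigvalsh(0.5 * (A + A.T))
    scale = max(abs(vals[0]), abs(vals[-1]), 1e-300)
    return float(vals[0] / scale)
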