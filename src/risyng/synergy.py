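"""Per-view synergy matrices, their eigenbasis, and relevance ranking.

The two representations of a view are fused by a convex combination
``H(beta) = beta * G + (1 - beta) * L`` with ``beta in [0, 1]``; both inputs
are PSD, so every ``H(beta)`` is PSD.  ``beta`` is selected by a provisional
cluster-validity scan: for each grid value the k-dimensional eigenbasis of
``H(beta)`` is clustered with k-means and scored with the cluster-averaged
silhouette; the grid maximiser wins (ties go to the smallest ``beta``).
Views are then ranked by that silhouette, most relevant first, which fixes
the order of the recursive integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from ._random import substream_seed
from .evaluation import silhouette_index

__all__ = [
    "SynergyView",
    "beta_grid",
    "synergy_matrix",
    "embed",
    "select_beta",
    "rank_views",
]


@dataclass
class SynergyView:
    """One view's selected synergy matrix and its diagnostic state."""

    name: str
    H: np.ndarray
    beta: float
    U_k: np.ndarray
    silhouette: float
    labels_provisional: np.ndarray


def beta_grid(alpha: float = 0.1) -> np.ndarray:
    """The scan grid {0, alpha, 2*alpha, ..., 1}; both endpoints included."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    steps = int(np.floor(1.0 / alpha + 1e-9))
    grid = np.minimum(np.arange(steps + 1) * alpha, 1.0)
    if not np.isclose(grid[-1], 1.0):
        grid = np.append(grid, 1.0)
    grid[-1] = 1.0
    return grid


def synergy_matrix(G: np.ndarray, L: np.ndarray, beta: float) -> np.ndarray:
    """Convex combination ``beta * G + (1 - beta) * L``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    G = np.asarray(G, dtype=float)
    L = np.asarray(L, dtype=float)
    if G.shape != L.shape:
        raise ValueError("G and L must have the same shape")
    H = beta * G + (1.0 - beta) * L
    return 0.5 * (H + H.T)


def embed(H: np.ndarray, k: int, mode: str = "smallest") -> np.ndarray:
    """Orthonormal eigenbasis of the k smallest (or largest) eigenvalues.

    Columns are ordered by eigenvalue (ascending for ``smallest``, descending
    for ``largest``); each column's sign is fixed so its largest-magnitude
    component is positive.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    if mode == "smallest":
        _, U = eigh(H, subset_by_index=[0, k - 1])
    elif mode == "largest":
        _, U = eigh(H, subset_by_index=[n - k, n - 1])
        U = U[:, ::-1]
    else:
        raise ValueError(f"mode must be 'smallest' or 'largest', got {mode!r}")
    return _fix_signs(np.ascontiguousarray(U))


def _fix_signs(U: np.ndarray) -> np.ndarray:
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def select_beta(
    G: np.ndarray,
    L: np.ndarray,
    k: int,
    alpha: float = 0.1,
    seed: int = 0,
    name: str = "view",
    mode: str = "smallest",
    kmeans_restarts: int = 10,
    t_max: int = 300,
) -> SynergyView:
    """Scan the beta grid and keep the synergy matrix with the best
    provisional silhouette.

    The scan's k-means uses one seeded substream per view, shared by every
    grid value, so identical synergy matrices score identically and the
    smallest-beta tie rule is exact up to round-off (scores within 1e-12
    count as ties).  A grid value whose clustering fails is skipped with a
    warning.
    """
    tie_tol = 1e-12
    best: SynergyView | None = None
    km_seed = substream_seed(seed, "beta_scan", name)
    for beta in beta_grid(alpha):
        H = synergy_matrix(G, L, float(beta))
        try:
            U = embed(H, k, mode=mode)
            km = KMeans(
                n_clusters=k,
                n_init=kmeans_restarts,
                max_iter=t_max,
                random_state=km_seed,
            ).fit(U)
            score = silhouette_index(U, km.labels_)
        except Exception as exc:  # noqa: BLE001 - degrade to a scan warning
            warnings.warn(
                f"view {name!r}: beta={beta:.3f} skipped ({exc})", stacklevel=2
            )
            continue
        if best is None or score > best.silhouette + tie_tol:
            best = SynergyView(
                name=name,
                H=H,
                beta=float(beta),
                U_k=U,
                silhouette=float(score),
                labels_provisional=km.labels_.copy(),
            )
    if best is None:
        raise RuntimeError(f"view {name!r}: every beta in the grid failed")
    return best


def rank_views(svs: list[SynergyView]) -> list[SynergyView]:
    """Sort views by provisional silhouette, most relevant first.

    The sort is stable, so ties keep the input order.
    """
    if not svs:
        raise ValueError("need at least one synergy view")
    return sorted(svs, key=lambda sv: -sv.silhouette)
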