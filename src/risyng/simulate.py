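"""Synthetic sample-matched multi-view data with planted cluster structure.

The generator emulates the *shape* of multi-omics benchmarks — a handful of
views over a shared sample set, imbalanced cluster sizes, per-view
dimensionality and noise, optionally pure-noise (irrelevant) views — while
making the planted structure explicit and controllable.  It deliberately
does not model realistic omics marginals (count overdispersion, beta-mixture
methylation); only the covariance/cluster geometry the algorithm consumes.

Cluster sizes are allocated deterministically by largest-remainder rounding
of the requested proportions, so size assertions stay exact; only the label
order is shuffled by the seed.

Two special-purpose generators build fixtures for the two representation
channels: :func:`make_correlation_clusters` plants groups that only the
correlation kernel (Gramian) can see, and :func:`make_location_clusters`
plants groups that only Euclidean geometry (the Laplacian channel) can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._random import substream_rng
from .io import MultiOmicsDataset, OmicsView

__all__ = [
    "ViewSpec",
    "SyntheticSpec",
    "make_multiview",
    "make_graph_fixture",
    "make_correlation_clusters",
    "make_location_clusters",
    "allocate_cluster_sizes",
]


@dataclass
class ViewSpec:
    """One view's shape: dimension, centroid separation (in units of
    noise_sd), noise level, and whether it carries the cluster signal."""

    d: int
    separation: float = 5.0
    noise_sd: float = 1.0
    relevant: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("view dimension must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-view dataset."""

    n: int
    k: int
    cluster_proportions: list[float]
    views: list[ViewSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.cluster_proportions, dtype=float)
        if len(p) != self.k:
            raise ValueError("cluster_proportions must have length k")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must be a simplex vector")
        if self.n < self.k:
            raise ValueError("need at least one sample per cluster")
        if not self.views:
            raise ValueError("need at least one view")


def allocate_cluster_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of ``n * proportions`` to integers
    summing to n."""
    target = n * np.asarray(proportions, dtype=float)
    sizes = np.floor(target).astype(int)
    rem = target - sizes
    short = n - sizes.sum()
    # hand the leftover samples to the largest remainders (stable on ties)
    for idx in np.argsort(-rem, kind="stable")[:short]:
        sizes[idx] += 1
    return sizes


def make_multiview(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, np.ndarray]:
    """Generate a sample-matched multi-view dataset and its planted labels.

    Relevant views place cluster centroids on a randomly rotated orthonormal
    frame scaled so every pairwise centroid distance equals
    ``separation * noise_sd``, then add isotropic Gaussian noise.
    Irrelevant views are pure noise.
    """
    sizes = allocate_cluster_sizes(spec.n, spec.cluster_proportions)
    labels = np.repeat(np.arange(spec.k), sizes)
    rng = substream_rng(spec.seed, "simulate", "labels")
    perm = rng.permutation(spec.n)
    labels = labels[perm]

    sample_ids = [f"S{i:04d}" for i in range(spec.n)]
    views = []
    for m, vs in enumerate(spec.views):
        vrng = substream_rng(spec.seed, "simulate", "view", m)
        X = vrng.normal(0.0, vs.noise_sd, size=(spec.n, vs.d))
        if vs.relevant and vs.separation > 0:
            frame = _orthonormal_frame(vrng, vs.d, spec.k)
            # orthonormal frame columns are sqrt(2) apart; rescale so the
            # pairwise centroid distance is separation * noise_sd exactly
            centroids = frame.T * (vs.separation * vs.noise_sd / np.sqrt(2.0))
            X = X + centroids[labels]
        views.append(
            OmicsView(
                name=f"view{m}",
                X=X.T,
                feature_ids=[f"V{m}_f{i}" for i in range(vs.d)],
                sample_ids=sample_ids,
                modality="other",
            )
        )
    return MultiOmicsDataset(views=views, sample_ids=sample_ids), labels


def _orthonormal_frame(rng: np.random.Generator, d: int, k: int) -> np.ndarray:
    """A d x k matrix with orthonormal columns, uniformly rotated."""
    if d < k:
        raise ValueError(f"view dimension {d} cannot host {k} orthonormal centroids")
    A = rng.normal(size=(d, k))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def make_graph_fixture(n: int, blocks: int, regular: bool = False) -> np.ndarray:
    """Block-diagonal similarity fixture for spectral property tests.

    Within-block weight 1 (self-loops included), zero across blocks: the
    normalised Laplacian then has eigenvalue 0 with multiplicity ``blocks``.
    With ``regular=True`` the blocks have equal size (n must divide evenly),
    giving a constant-degree graph on which the constant vector is an exact
    Laplacian null vector.
    """
    if blocks < 1 or n < blocks:
        raise ValueError("need 1 <= blocks <= n")
    if regular and n % blocks:
        raise ValueError("regular fixture needs blocks to divide n")
    sizes = allocate_cluster_sizes(n, np.full(blocks, 1.0 / blocks))
    W = np.zeros((n, n))
    start = 0
    for s in sizes:
        W[start : start + s, start : start + s] = 1.0
        start += s
    return W


def make_correlation_clusters(
    n: int,
    d: int = 60,
    n_clusters: int = 2,
    scale_range: tuple[float, float] = (1.0, 100.0),
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Groups visible to the correlation kernel but not to Euclidean
    distance.

    Each cluster has a fixed feature pattern; samples are that pattern times
    a wildly varying positive scale, plus a trace of noise.  Within-cluster
    correlation is near 1 (the Gramian is almost exactly block-constant, so
    its leading eigenspace collapses each cluster to a point) while the
    scale spread makes Euclidean distances as large within clusters as
    across them.

    Returns (X, labels) with X of shape d x n (features x samples).
    """
    rng = substream_rng(seed, "corr_fixture")
    sizes = allocate_cluster_sizes(n, np.full(n_clusters, 1.0 / n_clusters))
    labels = np.repeat(np.arange(n_clusters), sizes)
    patterns = _orthonormal_frame(rng, d, n_clusters)
    lo, hi = scale_range
    scales = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    X = patterns[:, labels] * scales[None, :]
    X += rng.normal(0.0, noise_sd, size=(d, n))
    return X, labels


def make_location_clusters(
    n: int,
    d: int = 40,
    n_clusters: int = 2,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain Gaussian location clusters: Euclidean geometry separates them.

    Returns (X, labels) with X of shape d x n (features x samples).
    """
    rng = substream_rng(seed, "loc_fixture")
    sizes = allocate_cluster_sizes(n, np.full(n_clusters, 1.0 / n_clusters))
    labels = np.repeat(np.arange(n_clusters), sizes)
    frame = _orthonormal_frame(rng, d, n_clusters)
    centroids = frame * (separation * noise_sd / np.sqrt(2.0))
    X = centroids[:, labels] + rng.normal(0.0, noise_sd, size=(d, n))
    return X, labels
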