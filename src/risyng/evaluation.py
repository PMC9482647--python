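"""Cluster validity indices, enrichment scores and the overlap test.

Internal indices (silhouette, Dunn, Davies-Bouldin, Xie-Beni) judge a
partition from the point geometry alone; external indices (F-measure, ARI,
NMI, Jaccard, purity) compare it with reference labels through the R x C
contingency table.  The silhouette here is the *cluster-averaged* form: the
mean over clusters of the mean silhouette width within each cluster, which
differs from the sample-averaged variant when cluster sizes are unequal.

Enrichment of a marker list is summarised by the mean -log10 adjusted p-value
over its significant terms (BPES/ES) and by the mean annotated-gene fraction
(AR); overlap with a curated gene catalogue is assessed with Fisher's exact
test on the 2 x 2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import fisher_exact
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "PartitionPair",
    "EnrichmentTermSet",
    "silhouette_index",
    "dunn_index",
    "davies_bouldin",
    "xie_beni",
    "f_measure",
    "adjusted_rand",
    "nmi",
    "jaccard_index",
    "purity",
    "enrichment_score",
    "annotation_ratio",
    "fisher_overlap",
]


# ---------------------------------------------------------------------------
# external indices


@dataclass
class PartitionPair:
    """A predicted partition against reference labels, plus their
    contingency table ``n_ij = |cluster_i ∩ class_j|``."""

    predicted: np.ndarray
    truth: np.ndarray
    contingency: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted)
        self.truth = np.asarray(self.truth)
        if self.predicted.shape != self.truth.shape or self.predicted.ndim != 1:
            raise ValueError("predicted and truth must be equal-length 1-D arrays")
        if self.predicted.size == 0:
            raise ValueError("empty partitions")
        _, pi = np.unique(self.predicted, return_inverse=True)
        _, ti = np.unique(self.truth, return_inverse=True)
        R, C = pi.max() + 1, ti.max() + 1
        tab = np.zeros((R, C), dtype=np.int64)
        np.add.at(tab, (pi, ti), 1)
        self.contingency = tab

    @property
    def n(self) -> int:
        return self.predicted.size


def _as_pair(
    pp: PartitionPair | Sequence, truth: Sequence | None = None
) -> PartitionPair:
    if isinstance(pp, PartitionPair):
        return pp
    if truth is None:
        raise TypeError("pass a PartitionPair or (predicted, truth) labels")
    return PartitionPair(np.asarray(pp), np.asarray(truth))


def f_measure(pp: PartitionPair | Sequence, truth: Sequence | None = None) -> float:
    """Information-retrieval F-measure of a clustering against classes.

    Each class is matched to the cluster maximising the harmonic mean of
    precision ``n_ij/n_i`` and recall ``n_ij/n_j``; the per-class maxima are
    averaged with weights ``n_j/n``.
    """
    pp = _as_pair(pp, truth)
    tab = pp.contingency.astype(float)
    ni = tab.sum(axis=1, keepdims=True)
    nj = tab.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = tab / ni
        rec = tab / nj
        f = np.where(tab > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float((nj / pp.n * f.max(axis=0)).sum())


def adjusted_rand(
    pp: PartitionPair | Sequence, truth: Sequence | None = None
) -> float:
    """Adjusted Rand index (chance-corrected pair agreement)."""
    pp = _as_pair(pp, truth)
    if pp.n < 2:
        raise ValueError("ARI needs at least two samples")
    return float(adjusted_rand_score(pp.truth, pp.predicted))


def nmi(pp: PartitionPair | Sequence, truth: Sequence | None = None) -> float:
    """Mutual information normalised by the arithmetic mean of entropies.

    Both partitions trivial (zero entropy) gives 0 by the 0/0 -> 0
    convention.
    """
    pp = _as_pair(pp, truth)
    if pp.contingency.shape == (1, 1):
        return 0.0
    return float(
        normalized_mutual_info_score(
            pp.truth, pp.predicted, average_method="arithmetic"
        )
    )


def jaccard_index(
    pp: PartitionPair | Sequence, truth: Sequence | None = None
) -> float:
    """Pair-counting Jaccard: co-clustered pairs shared by both partitions
    over pairs co-clustered in at least one (0 if neither has any)."""
    pp = _as_pair(pp, truth)
    if pp.n < 2:
        raise ValueError("Jaccard needs at least two samples")
    tab = pp.contingency
    both = _comb2(tab).sum()
    in_pred = _comb2(tab.sum(axis=1)).sum()
    in_truth = _comb2(tab.sum(axis=0)).sum()
    union = in_pred + in_truth - both
    return float(both / union) if union else 0.0


def purity(pp: PartitionPair | Sequence, truth: Sequence | None = None) -> float:
    """Fraction of samples in the majority class of their cluster."""
    pp = _as_pair(pp, truth)
    return float(pp.contingency.max(axis=1).sum() / pp.n)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


# ---------------------------------------------------------------------------
# internal indices


def _groups(points: np.ndarray, labels: Sequence) -> list[np.ndarray]:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and np.asarray(labels).size != 1:
        points = points.T
    labels = np.asarray(labels)
    if labels.size != points.shape[0]:
        raise ValueError("labels length must match number of points")
    return [np.flatnonzero(labels == u) for u in np.unique(labels)], points


def silhouette_index(points: np.ndarray, labels: Sequence) -> float:
    """Cluster-averaged silhouette index with Euclidean distances.

    ``s(x) = (b - a) / max(a, b)`` per sample, averaged within each cluster,
    then averaged (unweighted) over clusters.  Singletons score 0.
    """
    idx, pts = _groups(points, labels)
    if len(idx) < 2:
        raise ValueError("silhouette needs at least two clusters")
    D = squareform(pdist(pts))
    cluster_means = []
    for c, members in enumerate(idx):
        widths = []
        for i in members:
            if members.size == 1:
                widths.append(0.0)
                continue
            a = D[i, members].sum() / (members.size - 1)
            b = min(
                D[i, other].mean() for o, other in enumerate(idx) if o != c
            )
            denom = max(a, b)
            widths.append((b - a) / denom if denom > 0 else 0.0)
        cluster_means.append(float(np.mean(widths)))
    return float(np.mean(cluster_means))


def dunn_index(points: np.ndarray, labels: Sequence) -> float:
    """Minimum single-linkage inter-cluster distance over the maximum
    cluster diameter.  Higher is better."""
    idx, pts = _groups(points, labels)
    if len(idx) < 2:
        raise ValueError("Dunn needs at least two clusters")
    diam = 0.0
    for members in idx:
        if members.size > 1:
            diam = max(diam, pdist(pts[members]).max())
    if diam == 0.0:
        raise ValueError("all clusters are singletons or degenerate (zero diameter)")
    delta = min(
        cdist(pts[a], pts[b]).min()
        for i, a in enumerate(idx)
        for b in idx[i + 1 :]
    )
    return float(delta / diam)


def davies_bouldin(points: np.ndarray, labels: Sequence) -> float:
    """Mean over clusters of the worst (S_i + S_j) / M_ij ratio, where S is
    the mean distance to the centroid and M the centroid separation.
    Lower is better."""
    idx, pts = _groups(points, labels)
    if len(idx) < 2:
        raise ValueError("Davies-Bouldin needs at least two clusters")
    cents = np.array([pts[m].mean(axis=0) for m in idx])
    S = np.array(
        [np.linalg.norm(pts[m] - c, axis=1).mean() for m, c in zip(idx, cents)]
    )
    M = squareform(pdist(cents))
    C = len(idx)
    worst = []
    for i in range(C):
        ratios = []
        for j in range(C):
            if j == i:
                continue
            if M[i, j] == 0.0:
                raise ValueError("coincident centroids: Davies-Bouldin undefined")
            ratios.append((S[i] + S[j]) / M[i, j])
        worst.append(max(ratios))
    return float(np.mean(worst))


def xie_beni(points: np.ndarray, labels: Sequence) -> float:
    """Within-cluster scatter per sample over the smallest squared
    barycentre separation.  Lower is better."""
    idx, pts = _groups(points, labels)
    if len(idx) < 2:
        raise ValueError("Xie-Beni needs at least two clusters")
    cents = np.array([pts[m].mean(axis=0) for m in idx])
    wgss = sum(
        float(((pts[m] - c) ** 2).sum()) for m, c in zip(idx, cents)
    )
    sep = squareform(pdist(cents)) ** 2
    min_sep = min(
        sep[i, j] for i in range(len(idx)) for j in range(i + 1, len(idx))
    )
    if min_sep == 0.0:
        raise ValueError("coincident barycentres: Xie-Beni undefined")
    n = pts.shape[0]
    return float(wgss / n / min_sep)


# ---------------------------------------------------------------------------
# enrichment scores and overlap test


@dataclass
class EnrichmentTermSet:
    """Significant terms from an enrichment run: (term id, adjusted p-value,
    annotated gene count), plus the total number of genes submitted."""

    terms: list[tuple[str, float, int]]
    total_genes: int

    def __post_init__(self) -> None:
        if self.total_genes < 1:
            raise ValueError("total_genes must be >= 1")
        for t, p, g in self.terms:
            if not (0.0 < p <= 1.0):
                raise ValueError(f"term {t!r}: p-value {p} outside (0, 1]")
            if g < 0:
                raise ValueError(f"term {t!r}: negative gene count")


def enrichment_score(ts: EnrichmentTermSet) -> float:
    """Mean -log10 adjusted p-value over the significant terms."""
    if not ts.terms:
        raise ValueError("enrichment score undefined for an empty term set")
    return float(np.mean([-np.log10(p) for _, p, _ in ts.terms]))


def annotation_ratio(ts: EnrichmentTermSet) -> float:
    """Mean fraction of submitted genes annotated per significant term."""
    if not ts.terms:
        raise ValueError("annotation ratio undefined for an empty term set")
    T = len(ts.terms)
    return float(sum(g for _, _, g in ts.terms) / (T * ts.total_genes))


def fisher_overlap(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Exact hypergeometric p-value for the 2 x 2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    return float(fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
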