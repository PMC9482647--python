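"""Independent brute-force reference implementations for the validity
indices.

Everything here is written as plain loops over samples, pairs, or
contingency cells, deliberately sharing no code with the package, so the
package implementations can be checked against them exhaustively on small
inputs.
"""

import itertools
import math

import numpy as np


def contingency(pred, truth):
    ps, ts = sorted(set(pred)), sorted(set(truth))
    tab = [[0] * len(ts) for _ in ps]
    for p, t in zip(pred, truth):
        tab[ps.index(p)][ts.index(t)] += 1
    return tab


def pair_counts(pred, truth):
    """(a, b, c, d): pairs co-clustered in both / pred only / truth only /
    neither."""
    a = b = c = d = 0
    n = len(pred)
    for i, j in itertools.combinations(range(n), 2):
        sp, st = pred[i] == pred[j], truth[i] == truth[j]
        if sp and st:
            a += 1
        elif sp:
            b += 1
        elif st:
            c += 1
        else:
            d += 1
    return a, b, c, d


def ari_oracle(pred, truth):
    a, b, c, d = pair_counts(pred, truth)
    num = 2.0 * (a * d - b * c)
    den = (a + b) * (b + d) + (a + c) * (c + d)
    return num / den if den else 1.0


def nmi_oracle(pred, truth):
    n = len(pred)
    tab = contingency(pred, truth)
    mi = 0.0
    for row in tab:
        ni = sum(row)
        for j, nij in enumerate(row):
            nj = sum(r[j] for r in tab)
            if nij:
                mi += nij / n * math.log(nij * n / (ni * nj))
    hp = -sum(
        sum(r) / n * math.log(sum(r) / n) for r in tab if sum(r)
    )
    ht = -sum(
        (cj := sum(r[j] for r in tab)) / n * math.log(cj / n)
        for j in range(len(tab[0]))
        if sum(r[j] for r in tab)
    )
    denom = (hp + ht) / 2.0
    return mi / denom if denom > 0 else 0.0


def f_measure_oracle(pred, truth):
    n = len(pred)
    tab = contingency(pred, truth)
    total = 0.0
    for j in range(len(tab[0])):
        nj = sum(r[j] for r in tab)
        best = 0.0
        for i, row in enumerate(tab):
            nij, ni = row[j], sum(row)
            if nij:
                p, r = nij / ni, nij / nj
                best = max(best, 2 * p * r / (p + r))
        total += nj / n * best
    return total


def jaccard_oracle(pred, truth):
    n = len(pred)
    sp = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if pred[i] == pred[j]
    }
    st = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if truth[i] == truth[j]
    }
    union = sp | st
    return len(sp & st) / len(union) if union else 0.0


def purity_oracle(pred, truth):
    tab = contingency(pred, truth)
    return sum(max(row) for row in tab) / len(pred)


# ---------------------------------------------------------------------------
# internal indices


def _dist(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def silhouette_oracle(points, labels):
    points = [list(map(float, p)) for p in points]
    clusters = sorted(set(labels))
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    per_cluster = []
    for c in clusters:
        widths = []
        for i in members[c]:
            if len(members[c]) == 1:
                widths.append(0.0)
                continue
            a = sum(_dist(points[i], points[j]) for j in members[c] if j != i) / (
                len(members[c]) - 1
            )
            b = min(
                sum(_dist(points[i], points[j]) for j in members[o])
                / len(members[o])
                for o in clusters
                if o != c
            )
            widths.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        per_cluster.append(sum(widths) / len(widths))
    return sum(per_cluster) / len(per_cluster)


def dunn_oracle(points, labels):
    clusters = sorted(set(labels))
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    diam = max(
        (
            _dist(points[i], points[j])
            for c in clusters
            for i in members[c]
            for j in members[c]
            if i < j
        ),
        default=0.0,
    )
    delta = min(
        _dist(points[i], points[j])
        for a, b in itertools.combinations(clusters, 2)
        for i in members[a]
        for j in members[b]
    )
    return delta / diam


def davies_bouldin_oracle(points, labels):
    clusters = sorted(set(labels))
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    cent = {
        c: [sum(points[i][f] for i in members[c]) / len(members[c])
            for f in range(len(points[0]))]
        for c in clusters
    }
    S = {
        c: sum(_dist(points[i], cent[c]) for i in members[c]) / len(members[c])
        for c in clusters
    }
    total = 0.0
    for i in clusters:
        total += max(
            (S[i] + S[j]) / _dist(cent[i], cent[j]) for j in clusters if j != i
        )
    return total / len(clusters)


def xie_beni_oracle(points, labels):
    clusters = sorted(set(labels))
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    cent = {
        c: [sum(points[i][f] for i in members[c]) / len(members[c])
            for f in range(len(points[0]))]
        for c in clusters
    }
    wgss = sum(
        _dist(points[i], cent[c]) ** 2 for c in clusters for i in members[c]
    )
    min_sep = min(
        _dist(cent[a], cent[b]) ** 2
        for a, b in itertools.combinations(clusters, 2)
    )
    return wgss / len(points) / min_sep


def quadratic_form_oracle(W, d, f):
    """Brute-force double sum for the normalised-Laplacian quadratic form:
    0.5 * sum_ij w_ij (f_i/sqrt(d_i) - f_j/sqrt(d_j))^2."""
    n = len(d)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += W[i][j] * (
                f[i] / math.sqrt(d[i]) - f[j] / math.sqrt(d[j])
            ) ** 2
    return 0.5 * total


def random_labels(rng, n, k):
    """Random label vector guaranteed to use all k labels."""
    while True:
        lab = rng.integers(0, k, size=n)
        if len(np.unique(lab)) == k:
            return lab
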