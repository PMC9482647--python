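import numpy as np
import pytest

from risyng.io import OmicsView


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def view_from_matrix(X, name="v", modality="other", sample_prefix="s"):
    """Wrap a features x samples array in an OmicsView with generated IDs."""
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    return OmicsView(
        name=name,
        X=X,
        feature_ids=[f"{name}_f{i}" for i in range(d)],
        sample_ids=[f"{sample_prefix}{j}" for j in range(n)],
        modality=modality,
    )


@pytest.fixture
def make_view():
    return view_from_matrix


def random_spd_kernel(rng, n, scale=1.0):
    """A random PSD kernel with unit diagonal (for synergy-style tests)."""
    A = rng.normal(size=(n, n + 5))
    K = A @ A.T
    d = np.sqrt(np.diag(K))
    return scale * (K / np.outer(d, d))


def canonical_partitions(n, max_k):
    """All label vectors of length n in restricted-growth (first-occurrence)
    form with at most max_k distinct labels."""
    out = []

    def rec(prefix, used):
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for lab in range(min(used + 1, max_k)):
            rec(prefix + [lab], max(used, lab + 1))

    rec([0], 1)
    return out
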