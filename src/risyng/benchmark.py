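"""Runtime scaling measurement.

The pipeline's dominant cost is the beta scan's repeated full
eigendecompositions of the n x n synergy matrices, an O(M t_beta n^3) term;
degree/Laplacian assembly and pairwise distances add O(n^2) work and the
k-means calls O(n).  At moderate n the lower-order terms and per-call
overheads are far from negligible, so the observed log-log slope of wall
time against n sits below the asymptotic exponent; this module measures it.
"""

from __future__ import annotations

import time

import numpy as np

from .cluster import RISynG
from .simulate import SyntheticSpec, ViewSpec, make_multiview

__all__ = ["time_run", "scaling_slope"]


def _limit_threads():
    try:
        from threadpoolctl import threadpool_limits

        return threadpool_limits(limits=1)
    except Exception:  # pragma: no cover - threadpoolctl ships with sklearn
        import contextlib

        return contextlib.nullcontext()


def time_run(n: int, n_views: int = 2, k: int = 3, d: int = 50,
             seed: int = 0, repeats: int = 1) -> float:
    """Best-of-``repeats`` wall time of a full fit on an n-sample dataset.

    Timing is done with BLAS restricted to one thread so the measured trend
    reflects the serial operation count rather than parallel speedups.
    """
    spec = SyntheticSpec(
        n=n,
        k=k,
        cluster_proportions=[1.0 / k] * k,
        views=[ViewSpec(d=d, separation=5.0, noise_sd=1.0, relevant=True)
               for _ in range(n_views)],
        seed=seed,
    )
    data, _ = make_multiview(spec)
    model = RISynG(n_clusters=k, random_state=seed)
    best = np.inf
    with _limit_threads():
        for _ in range(repeats):
            t0 = time.perf_counter()
            model.fit(data)
            best = min(best, time.perf_counter() - t0)
    return float(best)


def scaling_slope(ns=(100, 200, 400), repeats: int = 2, seed: int = 0,
                  **kwargs) -> tuple[float, dict[int, float]]:
    """Least-squares slope of log(time) against log(n), plus raw timings."""
    times = {n: time_run(n, seed=seed, repeats=repeats, **kwargs) for n in ns}
    x = np.log(np.array(list(times), dtype=float))
    y = np.log(np.array(list(times.values())))
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, times
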