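"""Seed management.

A single master seed drives every stochastic step (provisional k-means inside
the beta scan, the final k-means, and the simulator).  Each consumer asks for a
named substream so that, e.g., adding a view does not perturb the random state
seen by the final clustering.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31  # sklearn random_state must be < 2**32; stay below 2**31


def substream_seed(master_seed: int, *names: object) -> int:
    """Derive a deterministic integer seed for a named substream.

    Parameters
    ----------
    master_seed : int
        The run-level seed.
    *names : str or int
        Hierarchical labels, e.g. ``("beta_scan", view_name, beta_index)``.

    Returns
    -------
    int in [0, 2**31).
    """
    key = zlib.crc32("/".join(str(n) for n in names).encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % _MOD)


def substream_rng(master_seed: int, *names: object) -> np.random.Generator:
    """A numpy Generator for a named substream of the master seed."""
    return np.random.default_rng(substream_seed(master_seed, *names))
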