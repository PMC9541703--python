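"""Random LD pruning: greedy maximal independent set in a sparse LD graph.

Variants are visited in a random order; a variant is kept unless an already
kept variant lies in its LD neighborhood.  The inner loop is numba-compiled
because it runs tens of thousands of times per lookup/fit construction.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _greedy_keep(indptr, indices, order, active):  # pragma: no cover - numba
    kept = np.zeros(active.size, dtype=np.bool_)
    for v in order:
        ok = True
        for k in range(indptr[v], indptr[v + 1]):
            j = indices[k]
            if active[j] and kept[j]:
                ok = False
                break
        if ok:
            kept[v] = True
    return kept


def random_prune(
    indptr: np.ndarray,
    indices: np.ndarray,
    subset: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return indices of a random maximal LD-independent subset of ``subset``.

    ``indptr``/``indices`` is a CSR adjacency over the full variant universe;
    ``subset`` holds the integer indices eligible for keeping.
    """
    n = indptr.size - 1
    active = np.zeros(n, dtype=np.bool_)
    active[subset] = True
    order = rng.permutation(subset).astype(np.int64)
    kept = _greedy_keep(indptr, indices.astype(np.int64), order, active)
    return np.flatnonzero(kept)
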