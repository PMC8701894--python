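"""Fast traversal of flattened regression-tree ensembles.

Trees are stored as parallel arrays (one row per tree, padded to the widest
tree): ``feature[b, k]`` is the split predictor index of node ``k`` in tree
``b`` (-1 for a leaf), ``threshold`` the cutpoint, ``left``/``right`` the
child node indices for ``x[feature] < threshold`` / ``>=``, and ``value`` the
leaf mean. A numba-compiled kernel is used when available; a vectorised
numpy traversal provides the identical result otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _ensemble_sum_py(X, feature, threshold, left, right, value, out):
    n_trees = feature.shape[0]
    n_rows = X.shape[0]
    for b in range(n_trees):
        for i in range(n_rows):
            node = 0
            f = feature[b, node]
            while f >= 0:
                if X[i, f] < threshold[b, node]:
                    node = left[b, node]
                else:
                    node = right[b, node]
                f = feature[b, node]
            out[i] += value[b, node]
    return out


if _HAVE_NUMBA:
    _ensemble_sum_jit = njit(cache=False)(_ensemble_sum_py)
else:  # pragma: no cover
    _ensemble_sum_jit = None


def _ensemble_sum_numpy(X, feature, threshold, left, right, value, out):
    n_trees = feature.shape[0]
    n_rows = X.shape[0]
    rows = np.arange(n_rows)
    for b in range(n_trees):
        node = np.zeros(n_rows, dtype=np.int64)
        f = feature[b, node]
        internal = f >= 0
        # best-first trees have depth <= number of nodes; loop until settled
        while internal.any():
            xv = X[rows, np.where(internal, f, 0)]
            nxt = np.where(xv < threshold[b, node], left[b, node], right[b, node])
            node = np.where(internal, nxt, node)
            f = feature[b, node]
            internal = f >= 0
        out += value[b, node]
    return out


def ensemble_predict(X, feature, threshold, left, right, value, learning_rate,
                     use_numba=True):
    """Sum of shrunken tree outputs, ``learning_rate * sum_b tree_b(x)``."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    out = np.zeros(X.shape[0], dtype=np.float64)
    if _HAVE_NUMBA and use_numba:
        _ensemble_sum_jit(X, feature, threshold, left, right, value, out)
    else:
        _ensemble_sum_numpy(X, feature, threshold, left, right, value, out)
    return learning_rate * out
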