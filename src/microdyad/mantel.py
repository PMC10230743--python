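"""Mantel permutation test between two dyadic matrices.

Used to check that mother-offspring status and social association are not
confounded before both enter the dyadic model: the observed statistic is the
Pearson correlation of the lower-triangle entries, and its null distribution
is built by jointly permuting the row/column labels of the second matrix.

The test is two-sided with the add-one permutation convention:
p = (1 + #{permutations with |r*| >= |r|}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _labelled(m) -> pd.DataFrame | None:
    if isinstance(m, pd.DataFrame):
        return m
    if isinstance(getattr(m, "data", None), pd.DataFrame):
        return m.data
    return None


def _as_array(m) -> np.ndarray:
    lab = _labelled(m)
    a = lab.to_numpy(dtype=float) if lab is not None else np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("Mantel test needs square matrices")
    if not np.allclose(a, a.T):
        raise ValueError("Mantel test needs symmetric matrices")
    return a


def mantel(
    m1, m2, n_perm: int = 9999, seed: int = 0, method: str = "sampled"
) -> tuple[float, float]:
    """Two-sided Mantel test; returns (r, p).

    Accepts numpy arrays, DataFrames, or wrapper objects with a ``.data``
    DataFrame (SriMatrix, SimilarityMatrix). Matrices must be square,
    symmetric and of equal size; if both are labelled, labels must agree.

    ``method="exact"`` enumerates all n! label permutations (the identity
    counts itself, so p = #{|r*| >= |r|} / n!); feasible for n <= 8 and
    useful as a permutation-free reference. The default draws ``n_perm``
    random permutations with the add-one convention.
    """
    a1 = _as_array(m1)
    a2 = _as_array(m2)
    if a1.shape != a2.shape:
        raise ValueError(f"matrix sizes differ: {a1.shape} vs {a2.shape}")
    lab1, lab2 = _labelled(m1), _labelled(m2)
    if lab1 is not None and lab2 is not None and not lab1.index.equals(lab2.index):
        raise ValueError("matrix labels differ; align individuals first")
    n = a1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 individuals")
    il = np.tril_indices(n, k=-1)
    v1 = a1[il]
    if np.std(v1) == 0:
        raise ValueError("first matrix is constant off-diagonal")
    r_obs = float(np.corrcoef(v1, a2[il])[0, 1])

    if method == "exact":
        from itertools import permutations
        from math import factorial

        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = 0
        for perm in permutations(range(n)):
            p_ix = np.asarray(perm)
            r_star = np.corrcoef(v1, a2[np.ix_(p_ix, p_ix)][il])[0, 1]
            if np.abs(r_star) >= np.abs(r_obs) - 1e-12:
                count += 1
        return r_obs, count / factorial(n)
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = np.corrcoef(v1, a2[np.ix_(perm, perm)][il])[0, 1]
        if np.abs(r_star) >= np.abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p
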