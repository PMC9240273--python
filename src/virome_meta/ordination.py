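"""Bray-Curtis dissimilarity, principal coordinates analysis, PERMANOVA.

The distance matrix is carried as a pandas DataFrame (samples x samples,
symmetric, zero diagonal).  PCoA uses classical double centering with a
deterministic axis-sign convention; PERMANOVA partitions squared
distances and assesses the pseudo-F by label permutation (Monte-Carlo by
default, exhaustive enumeration of distinct labelings on request).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "pcoa", "permanova", "PcoaResult", "PermanovaResult"]


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa matrix.

    d(x, y) = sum |x_t - y_t| / sum (x_t + y_t).
    """
    x = abundance.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = abundance.index[zero].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    return m


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray         # kept (positive) eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame, k: int = 2) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers B = -1/2 J D^2 J, eigendecomposes, and keeps the top-k
    positive eigenpairs; coordinates are eigenvectors scaled by the square
    root of their eigenvalues.  Proportion explained is relative to the sum
    of positive eigenvalues (negative eigenvalues, which Bray-Curtis can
    produce, are dropped from the denominator).  Each axis's sign is fixed
    so that its largest-magnitude coordinate is positive.
    """
    m = _check_distance(d)
    n = m.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (m**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    if not pos.any():
        raise ValueError("no positive eigenvalue; distances carry no metric structure")
    evals_pos = evals[pos]
    evecs_pos = evecs[:, pos]
    k_eff = min(k, evals_pos.size)
    coords = evecs_pos[:, :k_eff] * np.sqrt(evals_pos[:k_eff])
    for ax in range(k_eff):
        i_max = np.argmax(np.abs(coords[:, ax]))
        if coords[i_max, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    frame = pd.DataFrame(coords, index=d.index,
                         columns=[f"PCo{i + 1}" for i in range(k_eff)])
    return PcoaResult(
        coordinates=frame,
        eigenvalues=evals_pos[:k_eff],
        proportion_explained=evals_pos[:k_eff] / evals_pos.sum(),
    )


@dataclass(frozen=True)
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    ss_total: float
    ss_between: float
    ss_within: float


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_total, ss_between, ss_within


def permanova(d: pd.DataFrame, labels, n_perm: int = 999, seed: int = 0,
              method: str = "monte-carlo") -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous quantity
    per group; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).  The
    p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm) under random label
    permutation, or the exact fraction over all distinct labelings when
    ``method="exact"`` (small n only).
    """
    m = _check_distance(d)
    labels = np.asarray(labels)
    if labels.size != m.shape[0]:
        raise ValueError("labels must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = m**2
    f_obs, ss_t, ss_b, ss_w = _permanova_f(d2, codes, a)
    if method == "exact":
        count_ge = 0
        total = 0
        for perm in permutations(codes):
            total += 1
            f_perm, *_ = _permanova_f(d2, np.array(perm), a)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        n_used = total
    elif method == "monte-carlo":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_perm):
            f_perm, *_ = _permanova_f(d2, rng.permutation(codes), a)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        r2=ss_b / ss_t,
        pseudo_f=f_obs,
        p=p,
        n_perm=n_used,
        ss_total=ss_t,
        ss_between=ss_b,
        ss_within=ss_w,
    )
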