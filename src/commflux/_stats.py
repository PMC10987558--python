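"""Shared statistical primitives: rank-sum tests and permutation-based FDR.

The permutation FDR is a SAM-style plug-in estimate.  For every feature g
with observed two-sided rank-sum p-value p_g, B label permutations yield a
matrix of null p-values; the q-value is

    q_g = median_b #{null p in permutation b <= p_g} / max(1, #{observed p <= p_g})

clipped to [0, 1] and made monotone non-decreasing in p.  Null p-values use
the tie-corrected normal approximation so the permutation stream can be
fully vectorized; observed p-values use the exact distribution when the
combined sample is small and tie-free.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _as_group_mask(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly two groups required, got {uniq.tolist()}")
    return labels == uniq[0], uniq


def ranksum_pvalues(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column of X (samples × features).

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise (scipy's ``method='auto'``).
    A constant column carries no rank information and gets p = 1.
    """
    mask, _ = _as_group_mask(labels)
    X = np.asarray(X, dtype=float)
    a, b = X[mask], X[~mask]
    out = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        out[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    return out


def _null_ranksum_pvalues(
    X: np.ndarray, n_group1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm × n_features) matrix of rank-sum p-values under label permutation.

    Column ranks are permutation-invariant, so they are computed once and the
    permuted rank sums follow by indexing.  Tie-corrected normal
    approximation, no continuity correction.
    """
    X = np.asarray(X, dtype=float)
    n, G = X.shape
    ranks = stats.rankdata(X, axis=0)  # n × G, average ranks on ties

    # tie correction per feature
    tie_term = np.zeros(G)
    for j in range(G):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    n2 = n - n_group1
    mean = n_group1 * (n + 1) / 2.0
    var = n_group1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    pvals = np.ones((n_perm, G))
    informative = var > 0
    sd = np.sqrt(var[informative])
    for b in range(n_perm):
        idx = rng.permutation(n)[:n_group1]
        W = ranks[idx][:, informative].sum(axis=0)
        z = (W - mean) / sd
        pvals[b, informative] = 2.0 * stats.norm.sf(np.abs(z))
    return pvals


def permutation_fdr(
    p_obs: np.ndarray,
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """SAM-style plug-in permutation q-values for per-feature rank-sum tests."""
    mask, _ = _as_group_mask(labels)
    p_obs = np.asarray(p_obs, dtype=float)
    null_p = _null_ranksum_pvalues(X, int(mask.sum()), n_perm, rng)

    null_counts = np.empty((n_perm, p_obs.size))
    for b in range(n_perm):
        row = np.sort(null_p[b])
        null_counts[b] = np.searchsorted(row, p_obs, side="right")
    expected_false = np.median(null_counts, axis=0)

    sorted_p = np.sort(p_obs)
    observed = np.searchsorted(sorted_p, p_obs, side="right")
    q = expected_false / np.maximum(1, observed)
    q = np.clip(q, 0.0, 1.0)

    # monotone non-decreasing in p: running max in ascending-p order
    order = np.argsort(p_obs, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    return q


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p; degenerate (constant) input gives (0, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        return 0.0, 1.0
    return float(rho), float(p)
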