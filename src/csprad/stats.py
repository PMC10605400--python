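"""Statistical primitives for the stability-selection procedure.

Wilcoxon rank-sum association tests (exact for small tie-free samples,
normal approximation with tie and continuity corrections otherwise),
Benjamini-Hochberg step-up FDR control, and greedy Spearman redundancy
pruning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have n <= 10 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.  Identical constant groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def rank_sum_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-vectorized two-sided rank-sum p-values.

    ``X`` is (n_samples, n_features); ``y`` boolean/0-1 group labels.
    Uses the normal approximation with tie and continuity corrections for
    every column (the selection loop operates at n ~ 90 per trial, far past
    the exact-enumeration regime).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    n = X.shape[0]
    n1 = int(y.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(X, axis=0)
    r1 = ranks[y].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum over tied groups of (t^3 - t) per column, built
    # incrementally from run lengths of the column-sorted values
    sorted_x = np.sort(X, axis=0)
    same = sorted_x[1:] == sorted_x[:-1]
    tie_term = np.zeros(X.shape[1])
    size = np.ones(X.shape[1])
    for i in range(same.shape[0]):
        size = np.where(same[i], size + 1, 1.0)
        s = size - 1  # group size before this extension
        tie_term += np.where(same[i], 3 * s ** 2 + 3 * s, 0.0)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = np.where(sigma2 > 0, 2 * sps.norm.sf(np.maximum(z, 0.0)), 1.0)
    return np.clip(p, 0.0, 1.0)


def benjamini_hochberg(p_values, q: float) -> np.ndarray:
    """Step-up BH rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def spearman_prune(feature_matrix: np.ndarray, p_values, threshold: float = 0.5,
                   ) -> np.ndarray:
    """Greedy redundancy pruning: keep features by ascending p-value,
    discarding any later feature with \\|Spearman rho\\| > threshold against a
    kept one.  Returns a boolean keep-mask over columns.

    Constant columns have undefined rho and are treated as uncorrelated.
    """
    X = np.asarray(feature_matrix, dtype=float)
    p = np.asarray(p_values, dtype=float)
    n_feat = X.shape[1]
    if p.shape[0] != n_feat:
        raise ValueError("p_values must align with feature columns")
    if n_feat == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    if n_feat == 1:
        return np.ones(1, dtype=bool)
    ranks = sps.rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        logger.debug("constant feature column(s) treated as uncorrelated")
    centred = ranks - ranks.mean(axis=0)
    denom = np.outer(sd, sd) * X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (centred.T @ centred) / denom, 0.0)
    keep = np.zeros(n_feat, dtype=bool)
    discarded = np.zeros(n_feat, dtype=bool)
    for idx in order:
        if discarded[idx]:
            continue
        keep[idx] = True
        corr = np.abs(rho[idx]) > threshold
        corr[idx] = False
        discarded |= corr & ~keep
    return keep
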