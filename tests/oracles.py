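"""Independent brute-force enumeration oracles for the texture matrices.

Everything here is written with explicit Python loops over voxels, pairs,
runs, zones and neighbourhoods — no shared code with the vectorized
implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEIGHBORS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3)
                if d != (0, 0, 0)]


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def oracle_glcm(labels, mask, direction, ng):
    """Symmetric co-occurrence counts by exhaustive voxel-pair enumeration."""
    m = np.zeros((ng, ng))
    shape = labels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(i + d for i, d in zip(idx, direction))
        if _in_bounds(nb, shape) and mask[nb]:
            i, j = labels[idx] - 1, labels[nb] - 1
            m[i, j] += 1
            m[j, i] += 1
    return m


def oracle_glrlm(labels, mask, direction, ng, max_len):
    """Run-length counts by walking every run start along the direction."""
    m = np.zeros((ng, max_len))
    shape = labels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        prev = tuple(i - d for i, d in zip(idx, direction))
        if (_in_bounds(prev, shape) and mask[prev]
                and labels[prev] == labels[idx]):
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + d for i, d in zip(cur, direction))
            if (_in_bounds(nxt, shape) and mask[nxt]
                    and labels[nxt] == labels[idx]):
                length += 1
                cur = nxt
            else:
                break
        m[labels[idx] - 1, length - 1] += 1
    return m


def oracle_glszm(labels, mask, ng):
    """Zone sizes via explicit 26-connected flood fill; returns (level, size)
    count matrix padded to the largest zone."""
    shape = labels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if not mask[idx] or seen[idx]:
            continue
        level = labels[idx]
        stack, size = [idx], 0
        seen[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                nb = tuple(i + dd for i, dd in zip(cur, d))
                if (_in_bounds(nb, shape) and mask[nb] and not seen[nb]
                        and labels[nb] == level):
                    seen[nb] = True
                    stack.append(nb)
        zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((ng, max_size))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def oracle_gldm(labels, mask, ng, alpha=0):
    """Dependence counts (stored at 1 + #dependent neighbours) by explicit
    neighbourhood loops."""
    shape = labels.shape
    entries = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        dep = 0
        for d in NEIGHBORS_26:
            nb = tuple(i + dd for i, dd in zip(idx, d))
            if (_in_bounds(nb, shape) and mask[nb]
                    and abs(int(labels[nb]) - int(labels[idx])) <= alpha):
                dep += 1
        entries.append((labels[idx], dep + 1))
    max_dep = max(j for _, j in entries)
    m = np.zeros((ng, max_dep))
    for i, j in entries:
        m[i - 1, j - 1] += 1
    return m


def oracle_ngtdm(labels, mask, ng):
    """Per-level (n_i, s_i) by explicit neighbourhood averaging."""
    shape = labels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        vals = []
        for d in NEIGHBORS_26:
            nb = tuple(i + dd for i, dd in zip(idx, d))
            if _in_bounds(nb, shape) and labels[nb] > 0:
                vals.append(labels[nb])
        if not vals:
            continue
        lev = labels[idx]
        n[lev - 1] += 1
        s[lev - 1] += abs(lev - sum(vals) / len(vals))
    return n, s


# --- independent loop-written feature formulas on count matrices ------------

def oracle_cluster_shade(counts):
    p = counts / counts.sum()
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_y = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    return sum(((i + 1) + (j + 1) - mu_x - mu_y) ** 3 * p[i, j]
               for i in range(ng) for j in range(ng))


def oracle_lrhgle(counts):
    nr = counts.sum()
    return sum(counts[i, j] * (i + 1) ** 2 * (j + 1) ** 2
               for i in range(counts.shape[0])
               for j in range(counts.shape[1])) / nr


def oracle_srhgle(counts):
    nr = counts.sum()
    return sum(counts[i, j] * (i + 1) ** 2 / (j + 1) ** 2
               for i in range(counts.shape[0])
               for j in range(counts.shape[1])) / nr


def oracle_glv(counts):
    nr = counts.sum()
    p = counts / nr
    mu = sum((i + 1) * p[i, j] for i in range(p.shape[0])
             for j in range(p.shape[1]))
    return sum(p[i, j] * ((i + 1) - mu) ** 2 for i in range(p.shape[0])
               for j in range(p.shape[1]))


def oracle_lglze(counts):
    nr = counts.sum()
    return sum(counts[i, j] / (i + 1) ** 2 for i in range(counts.shape[0])
               for j in range(counts.shape[1])) / nr


def oracle_hgle(counts):
    nr = counts.sum()
    return sum(counts[i, j] * (i + 1) ** 2 for i in range(counts.shape[0])
               for j in range(counts.shape[1])) / nr


def oracle_wilcoxon_exact(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of group assignments
    (requires no ties)."""
    pooled = sorted(list(a) + list(b))
    n, na = len(pooled), len(a)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    mean = na * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total
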