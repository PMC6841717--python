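"""Independent brute-force reference implementations used as test oracles.

These deliberately favour clarity over speed (explicit loops, per-box
refitting, full enumeration) and share no code with the package paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_rmsf(u: np.ndarray, scales, delta_l0: int = 1) -> np.ndarray:
    """F(l) by direct enumeration of every offset l0 at the given stride."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    y = np.zeros(n + 1)
    for i in range(n):
        y[i + 1] = y[i] + u[i]
    out = []
    for l in scales:
        dys = []
        l0 = 0
        while l0 + l <= n:
            dys.append(y[l0 + l] - y[l0])
            l0 += delta_l0
        dys = np.asarray(dys)
        out.append(np.sqrt(np.mean(dys**2) - np.mean(dys) ** 2))
    return np.asarray(out)


def brute_dfa(u: np.ndarray, box_sizes, order: int = 1) -> np.ndarray:
    """D(n) recomputed box by box with an independent polynomial fit."""
    u = np.asarray(u, dtype=float)
    z = np.cumsum(u - np.mean(u))
    out = []
    for size in box_sizes:
        m = len(z) // size
        ss = 0.0
        for b in range(m):
            seg = z[b * size : (b + 1) * size]
            x = np.arange(size, dtype=float)
            coeffs = np.polyfit(x, seg, order)
            ss += float(np.sum((seg - np.polyval(coeffs, x)) ** 2))
        out.append(np.sqrt(ss / (m * size)))
    return np.asarray(out)


def brute_msd_radial(positions: np.ndarray, tau_max: int) -> np.ndarray:
    """Time-averaged squared radial increments by double loop."""
    p = np.asarray(positions, dtype=float) - positions[0]
    r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
    n = len(r)
    out = []
    for tau in range(1, tau_max + 1):
        acc = 0.0
        for t in range(n - tau):
            acc += (r[t + tau] - r[t]) ** 2
        out.append(acc / (n - tau))
    return np.asarray(out)


def brute_msd_vector(positions: np.ndarray, tau_max: int) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    n = len(p)
    out = []
    for tau in range(1, tau_max + 1):
        acc = 0.0
        for t in range(n - tau):
            acc += float(np.sum((p[t + tau] - p[t]) ** 2))
        out.append(acc / (n - tau))
    return np.asarray(out)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed from scratch (1-based, ties averaged)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every label assignment."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = ranks[: len(a)].sum()
    n = len(pooled)
    le = ge = total = 0
    for combo in combinations(range(n), len(a)):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)
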