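"""Independent brute-force oracles used to verify the statistical kernels.

These deliberately avoid the code paths they check: the U-test oracle
enumerates every assignment of the pooled sample, the Welch and Pearson
oracles evaluate the closed-form textbook formulas, the BH oracle applies
the step-up rule literally, and the knee oracle scans every interior point.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def u_statistic(a, b) -> float:
    """Mann–Whitney U of sample ``a`` via direct pair counting (midranks)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_mwu_p(a, b) -> float:
    """Exact two-sided p by enumerating all C(n, n_a) group assignments.

    Two-sided p = P(U ≤ u_low) + P(U ≥ n_a·n_b − u_low) with
    u_low = min(u, n_a·n_b − u), over the permutation distribution of U.
    Valid for tie-free data (where the distribution is symmetric).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    nm = n_a * len(b)
    u_obs = u_statistic(a, b)
    u_low = min(u_obs, nm - u_obs)
    idx = range(len(pooled))
    count = total = 0
    for subset in combinations(idx, n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(subset)] = True
        u = u_statistic(pooled[mask], pooled[~mask])
        if u <= u_low or u >= nm - u_low:
            count += 1
        total += 1
    return min(count / total, 1.0)


def permutation_mwu_p(a, b, n_perm: int, seed: int) -> float:
    """Monte-Carlo two-sided p for larger samples (same tail definition)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    nm = n_a * len(b)
    u_obs = u_statistic(a, b)
    u_low = min(u_obs, nm - u_obs)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        u = u_statistic(perm[:n_a], perm[n_a:])
        if u <= u_low or u >= nm - u_low:
            hits += 1
    return hits / n_perm


def welch_oracle(a, b):
    """Closed-form Welch t, Welch–Satterthwaite df, and two-sided p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_oracle(x, y) -> float:
    """Pearson r from the raw-moment formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = (x * y).sum() - n * x.mean() * y.mean()
    den = np.sqrt(
        ((x * x).sum() - n * x.mean() ** 2) * ((y * y).sum() - n * y.mean() ** 2)
    )
    return float(num / den)


def bh_oracle(p):
    """Literal BH step-up: sort, scale by m/k, enforce monotone, unsort."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def knee_oracle(curve) -> int:
    """Scan every interior rank for the max distance to the endpoint chord."""
    v = np.asarray(curve, float)
    m = len(v)
    if m < 3:
        return m
    x1, y1, x2, y2 = 1.0, v[0], float(m), v[-1]
    norm = np.hypot(x2 - x1, y2 - y1)
    best_rank, best_dist = None, -1.0
    for rank in range(2, m):  # 1-based interior ranks
        x0, y0 = float(rank), v[rank - 1]
        dist = abs((y2 - y1) * x0 - (x2 - x1) * y0 + x2 * y1 - y2 * x1) / norm
        if dist > best_dist + 1e-15:
            best_rank, best_dist = rank, dist
    return best_rank
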