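"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by direct enumeration or naive loops,
deliberately sharing no code path with the library implementation.
"""

import itertools
import math

import numpy as np


def brute_force_cell_loglik(y_by_year, p_by_year, psi1, gamma, epsilon):
    """Enumerate every latent occupancy path (z_1..z_T) in {0,1}^T."""
    T = len(y_by_year)
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        pr = psi1 if path[0] == 1 else 1.0 - psi1
        for t in range(1, T):
            if path[t - 1] == 1:
                pr *= (1.0 - epsilon) if path[t] == 1 else epsilon
            else:
                pr *= gamma if path[t] == 1 else (1.0 - gamma)
        for t, (ys, ps) in enumerate(zip(y_by_year, p_by_year)):
            for y, p in zip(ys, ps):
                if path[t] == 1:
                    pr *= p if y == 1 else (1.0 - p)
                elif y == 1:
                    pr = 0.0
        total += pr
    return math.log(total) if total > 0 else -math.inf


def double_loop_waic(loglik):
    """Unvectorized WAIC: explicit loops over units and draws."""
    S, N = loglik.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(N):
        col = [loglik[s, i] for s in range(S)]
        mean_lik = sum(math.exp(v) for v in col) / S
        lppd += math.log(mean_lik)
        mean_ll = sum(col) / S
        p_waic += sum((v - mean_ll) ** 2 for v in col) / (S - 1)
    return -2.0 * (lppd - p_waic), lppd, p_waic


def pairwise_auc(scores, labels):
    """All-pairs concordance count with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pixel_pair_edge_density(grid, pixel_size, focal, nodata=-9999):
    """Edge density by explicit enumeration of all interior pixel pairs."""
    grid = np.asarray(grid)
    nr, nc = grid.shape
    focal = set(focal)
    edges = 0
    for i in range(nr):
        for j in range(nc):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < nr and jj < nc:
                    a, b = grid[i, j], grid[ii, jj]
                    if a == nodata or b == nodata:
                        continue
                    if (a in focal) != (b in focal):
                        edges += 1
    area_ha = (grid != nodata).sum() * pixel_size**2 / 10_000.0
    return edges * pixel_size / area_ha


def pixel_pair_contagion(grid, nodata=-9999):
    """Contagion by explicit pixel-pair enumeration (double count)."""
    grid = np.asarray(grid)
    valid = grid[grid != nodata]
    classes = sorted(set(int(v) for v in valid))
    m = len(classes)
    if m < 2:
        raise ValueError("single class")
    idx = {c: i for i, c in enumerate(classes)}
    P = np.array([(valid == c).sum() for c in classes], dtype=float)
    P /= P.sum()
    g = np.zeros((m, m))
    nr, nc = grid.shape
    for i in range(nr):
        for j in range(nc):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < nr and jj < nc:
                    a, b = grid[i, j], grid[ii, jj]
                    if a == nodata or b == nodata:
                        continue
                    g[idx[int(a)], idx[int(b)]] += 1
                    g[idx[int(b)], idx[int(a)]] += 1
    acc = 0.0
    for i in range(m):
        row = g[i].sum()
        for k in range(m):
            if row > 0 and g[i, k] > 0:
                q = P[i] * g[i, k] / row
                acc += q * math.log(q)
    return (1.0 + acc / (2.0 * math.log(m))) * 100.0


def sorted_order_quantiles(draws, qs=(0.025, 0.975)):
    """Empirical quantiles via explicit sorting and linear interpolation."""
    x = sorted(float(v) for v in draws)
    n = len(x)
    out = []
    for q in qs:
        h = (n - 1) * q
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return out
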