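"""Independent reference implementations used only as test oracles.

Everything here is deliberately written in the most direct way possible
(per-point solves, brute-force enumeration, dense grid search) and
shares no code with the package's computation paths.
"""

import itertools

import numpy as np
from scipy import stats as sps


def oracle_loess_point(x, y, x0, span, degree):
    """Tricube-weighted local polynomial fit at one point via explicit
    normal equations."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    q = min(max(int(np.floor(span * n)), degree + 2), n)
    dists = sorted(abs(xi - x0) for xi in x)
    h = dists[q - 1]
    if h == 0:
        vals = [yi for xi, yi in zip(x, y) if xi == x0]
        return sum(vals) / len(vals)
    pts = []
    for xi, yi in zip(x, y):
        u = abs(xi - x0) / h
        w = (1 - u**3) ** 3 if u < 1 else 0.0
        if w > 0:
            pts.append((xi - x0, yi, w))
    p = degree + 1
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    for dx, yi, w in pts:
        row = np.array([dx**k for k in range(p)])
        xtx += w * np.outer(row, row)
        xty += w * row * yi
    return np.linalg.solve(xtx, xty)[0]


def grid_search_sse(freqs, velocities, exponent, f0_grid, q_grid):
    """Exhaustive (f0, Q) grid search with the amplitude solved in closed
    form per grid point; returns the minimal SSE found."""
    w = 2 * np.pi * np.asarray(freqs, float)
    v = np.asarray(velocities, float)
    vv = float(v @ v)
    best = np.inf
    for q in q_grid:
        w0 = 2 * np.pi * np.asarray(f0_grid, float)[:, None]
        g = w**exponent / np.sqrt((w0**2 - w**2) ** 2 + (w * w0 / q) ** 2)
        vg = g @ v
        gg = (g * g).sum(axis=1)
        a = np.maximum(vg / gg, 0.0)
        sse = vv - 2 * a * vg + a * a * gg
        best = min(best, float(sse.min()))
    return best


def enumerate_signed_rank_p(d):
    """Two-sided exact signed-rank p over all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([1, -1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s > 0))
    stats = np.array(stats)
    p_low = np.mean(stats <= t_obs + 1e-12)
    p_high = np.mean(stats >= t_obs - 1e-12)
    return min(1.0, 2 * min(p_low, p_high))


def enumerate_rank_sum_p(x, y):
    """Two-sided exact rank-sum p over all group-label assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    n = len(pooled)
    mid = nx * (n - nx) / 2
    us = []
    for idx in itertools.combinations(range(n), nx):
        r = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(abs(r - mid))
    return min(1.0, float(np.mean(np.array(us) >= abs(u_obs - mid) - 1e-12)))
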