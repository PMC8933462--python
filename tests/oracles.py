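"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written the slow, literal way (explicit
loops, full enumerations) and never shares code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def disk_footprint(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y) <= radius * radius


# ---------------------------------------------------------------------------
# global thresholds

def naive_huang(hist) -> int:
    h = np.asarray(hist, dtype=float)
    g = np.arange(256)
    occ = np.nonzero(h)[0]
    c = occ[-1] - occ[0]
    best, best_f = None, np.inf
    for t in range(occ[0], occ[-1]):
        n0 = h[:t + 1].sum()
        n1 = h[t + 1:].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (h[:t + 1] * g[:t + 1]).sum() / n0
        mu1 = (h[t + 1:] * g[t + 1:]).sum() / n1
        f = 0.0
        for gi in range(256):
            if h[gi] == 0:
                continue
            mu = mu0 if gi <= t else mu1
            u = 1.0 / (1.0 + abs(gi - mu) / c)
            if u < 1.0:
                f += h[gi] * (-(u * math.log(u) + (1 - u) * math.log(1 - u)))
        if f < best_f - 1e-12:
            best_f, best = f, t
    return best


def naive_kapur(hist) -> int:
    h = np.asarray(hist, dtype=float)
    p = h / h.sum()
    occ = np.nonzero(h)[0]
    best, best_h = None, -np.inf
    for t in range(occ[0], occ[-1]):
        p0 = p[:t + 1].sum()
        p1 = p[t + 1:].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = -sum(pi / p0 * math.log(pi / p0) for pi in p[:t + 1] if pi > 0)
        h1 = -sum(pi / p1 * math.log(pi / p1) for pi in p[t + 1:] if pi > 0)
        if h0 + h1 > best_h + 1e-12:
            best_h, best = h0 + h1, t
    return best


# ---------------------------------------------------------------------------
# local thresholds

def naive_local_median(img: np.ndarray, radius: int) -> np.ndarray:
    pad = np.pad(img, radius, mode="edge")
    fp = disk_footprint(radius)
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1][fp]
            out[i, j] = img[i, j] > np.median(window)
    return out


def naive_phansalkar(img: np.ndarray, radius: int, k=0.25, r=0.5,
                     p=2.0, q=10.0) -> np.ndarray:
    pad = np.pad(img, radius, mode="edge")
    fp = disk_footprint(radius)
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1][fp]
            m = window.mean()
            s = window.std()
            t = m * (1.0 + p * math.exp(-q * m) + k * (s / r - 1.0))
            out[i, j] = img[i, j] > t
    return out


# ---------------------------------------------------------------------------
# statistics

def wilcoxon_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    n = d.size
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w + 1e-9:
            count += 1
    return w, min(1.0, 2.0 * count / 2 ** n)


def friedman_statistic(values: np.ndarray) -> float:
    """Classic tie-corrected Friedman Q of an n x k matrix."""
    from scipy.stats import rankdata
    v = np.asarray(values, float)
    n, k = v.shape
    ranks = np.vstack([rankdata(row) for row in v])
    rbar = (k + 1) / 2.0
    denom = ((ranks - rbar) ** 2).sum()
    if denom == 0:
        return 0.0
    return n * n * (k - 1) * ((ranks.mean(axis=0) - rbar) ** 2).sum() / denom


def friedman_permutation_p(values: np.ndarray) -> float:
    """Exact permutation p for the Friedman test (small n, k only)."""
    v = np.asarray(values, float)
    n, k = v.shape
    q_obs = friedman_statistic(v)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        arranged = np.vstack([v[i, list(perms[ci])] for i, ci in enumerate(combo)])
        if friedman_statistic(arranged) >= q_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def rm_anova_direct(values: np.ndarray) -> tuple[float, float]:
    """Textbook sums-of-squares one-way repeated-measures ANOVA."""
    from scipy.stats import f as fdist
    v = np.asarray(values, float)
    n, k = v.shape
    grand = v.mean()
    ss_subj = sum(k * (v[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (v[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    return f, float(fdist.sf(f, df1, df2))
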