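"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles (exhaustive
enumeration, naive re-scan, dense matrices or dense quadrature) and stays
independent of the implementation path it checks.
"""

import itertools

import numpy as np
from scipy import integrate
from scipy.optimize import minimize_scalar
from scipy.stats import cauchy, nct, rankdata, t as t_dist


def upgma_rescan(D: np.ndarray):
    """Naive O(n^3) average linkage: re-average all cross-pair leaf
    distances between every cluster pair at every step.  Tie-break: lowest
    (creation-order) cluster index pair."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    order = list(range(n))
    heights = []
    next_id = n
    while len(order) > 1:
        best = None
        for ai, a in enumerate(order):
            for b in order[ai + 1:]:
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        order = [c for c in order if c not in (a, b)] + [next_id]
        next_id += 1
    return np.array(heights)


def rm_anova_ss(cells: dict):
    """Full sums-of-squares two-factor repeated-measures ANOVA (2x2 within).

    Factor A = synchrony (sync/async), factor B = person (self/friend).
    Returns dict of F statistics computed from the SS decomposition with
    effect-specific subject-interaction error terms.
    """
    y = np.stack([
        [cells["syncSelf"], cells["syncFriend"]],
        [cells["asyncSelf"], cells["asyncFriend"]],
    ])  # shape (A, B, subjects)
    A, B, S = y.shape
    gm = y.mean()
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_s = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=2)
    m_as = y.mean(axis=1)
    m_bs = y.mean(axis=0)
    ss_a = B * S * ((m_a - gm) ** 2).sum()
    ss_b = A * S * ((m_b - gm) ** 2).sum()
    ss_ab = S * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = B * ((m_as - m_a[:, None] - m_s[None, :] + gm) ** 2).sum()
    ss_bs = A * ((m_bs - m_b[:, None] - m_s[None, :] + gm) ** 2).sum()
    resid = (y - m_ab[:, :, None] - m_as[:, None, :] - m_bs[None, :, :]
             + m_a[:, None, None] + m_b[None, :, None] + m_s[None, None, :]
             - gm)
    ss_abs = (resid ** 2).sum()
    dfe = S - 1
    return {
        "F_synchrony": (ss_a / (A - 1)) / (ss_as / ((A - 1) * dfe)),
        "F_person": (ss_b / (B - 1)) / (ss_bs / ((B - 1) * dfe)),
        "F_interaction": (ss_ab / 1) / (ss_abs / dfe),
    }


def wilcoxon_enumerate(diffs):
    """Exact two-sided p of the signed-rank sum by enumerating all 2^n sign
    assignments over the realized mid-ranks (zero diffs dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product([False, True], repeat=n)])
    p_low = (ws <= w_obs + 1e-12).mean()
    p_high = (ws >= w_obs - 1e-12).mean()
    return w_obs, min(1.0, 2 * min(p_low, p_high))


def reml_dense(y, X, groups):
    """Grid + refined profile-likelihood REML with explicit dense matrices."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    Z = np.zeros((len(y), len(labels)))
    Z[np.arange(len(y)), idx] = 1.0
    n, p = X.shape

    def neg_reml(lam):
        V = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        rss = r @ Vi @ r
        sigma2 = rss / (n - p)
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                      + ldV + ldX - p * np.log(sigma2))

    grid = np.concatenate([[0.0], np.logspace(-6, 6, 200)])
    vals = [neg_reml(l) for l in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, max(hi, lo + 1e-12)),
                          method="bounded", options={"xatol": 1e-12})
    lam = res.x if res.fun < vals[k] else grid[k]
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = (r @ Vi @ r) / (n - p)
    return {"lam": float(lam), "var_within": float(sigma2),
            "var_between": float(lam * sigma2), "beta": beta}


def jzs_bf01_trapezoid(t, n, r=np.sqrt(2) / 2, n_points=1_000_000, span=40.0):
    """Dense-trapezoid JZS Bayes factor over delta in [-span*r, span*r]."""
    df = n - 1
    delta = np.linspace(-span * r, span * r, n_points)
    f = nct.pdf(t, df, delta * np.sqrt(n)) * cauchy.pdf(delta, 0, r)
    bf10 = np.trapezoid(f, delta) / t_dist.pdf(t, df)
    return 1.0 / bf10


def spearman_permutation_p(x, y):
    """Exact two-sided permutation p-value of Spearman rho (all n! orders)."""
    rx = rankdata(x)
    ry = rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, np.array(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def corr_bf01_trapezoid(rho, n, n_points=200_001):
    """Dense-trapezoid Jeffreys-type correlation Bayes factor (uniform prior)."""
    p = np.linspace(-1 + 1e-9, 1 - 1e-9, n_points)
    lik = (1 - p ** 2) ** ((n - 1) / 2.0) / (1 - p * rho) ** (n - 1.5)
    bf10 = np.trapezoid(0.5 * lik, p) / 1.0  # lik(0) = 1
    return 1.0 / bf10
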