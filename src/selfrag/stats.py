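"""Inferential layer: paired tests, within-subject 2x2 ANOVA, rank
statistics, JZS Bayes factors, and single-mediator bootstrap mediation.

The Bayes factor follows the default JZS construction for a one-sample or
paired design: a Cauchy prior with scale r (default sqrt(2)/2 = 0.7071) on
the standardized effect delta, so

    BF10 = [ integral T_{n-1}(t | delta * sqrt(n)) Cauchy(delta; 0, r) d delta ]
           / T_{n-1}(t | 0)

evaluated by adaptive quadrature after the substitution delta = r tan(theta)
(finite domain, absolute tolerance 1e-8).  BF01 = 1 / BF10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import cauchy, f as f_dist, nct, norm, rankdata, t as t_dist

DEFAULT_PRIOR_SCALE = float(np.sqrt(2) / 2)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_two_sided: float
    mean_diff: float
    n: int


@dataclass
class Anova2x2Result:
    F_interaction: float
    F_synchrony: float
    F_person: float
    df: tuple
    p_interaction: float
    p_synchrony: float
    p_person: float


@dataclass
class BayesFactorResult:
    bf01: float
    t: float
    n: int
    prior_scale: float


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_prime: float
    indirect_ab: float
    z: float
    p_sobel: float
    boot_ci: tuple
    n_boot: int
    seed: int
    n: int


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t test (one-sample t on the differences x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    return PairedTestResult(t=float(t), df=n - 1,
                            p_two_sided=float(2 * t_dist.sf(abs(t), n - 1)),
                            mean_diff=float(d.mean()), n=n)


def anova_2x2_within(cells: dict) -> Anova2x2Result:
    """Balanced 2x2 within-subject ANOVA via contrast paired t statistics.

    ``cells`` maps the four condition names (syncSelf, asyncSelf,
    syncFriend, asyncFriend) to equal-length per-participant arrays.  Each
    effect F with df (1, n-1) equals the squared one-sample t of its
    contrast; this identity is exact in the balanced design.
    """
    need = ("syncSelf", "asyncSelf", "syncFriend", "asyncFriend")
    arrs = {}
    for k in need:
        if k not in cells:
            raise ValueError(f"missing cell {k}")
        arrs[k] = np.asarray(cells[k], dtype=float)
    n = len(arrs["syncSelf"])
    if any(len(a) != n for a in arrs.values()):
        raise ValueError("unequal cell lengths")
    aS, sS = arrs["asyncSelf"], arrs["syncSelf"]
    aF, sF = arrs["asyncFriend"], arrs["syncFriend"]

    def contrast_F(c):
        m = c.mean()
        sd = c.std(ddof=1)
        if sd == 0:
            return 0.0
        return float((m / (sd / np.sqrt(n))) ** 2)

    F_sync = contrast_F((aS + aF) - (sS + sF))
    F_pers = contrast_F((aS + sS) - (aF + sF))
    F_int = contrast_F((aS - sS) - (aF - sF))
    p = lambda F: float(f_dist.sf(F, 1, n - 1))
    return Anova2x2Result(F_interaction=F_int, F_synchrony=F_sync,
                          F_person=F_pers, df=(1, n - 1),
                          p_interaction=p(F_int), p_synchrony=p(F_sync),
                          p_person=p(F_pers))


def _signed_rank_exact_cdf(ranks2: np.ndarray):
    """Null distribution of W+ with (doubled, integer) mid-ranks."""
    total = int(ranks2.sum())
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[:total + 1 - r]
        probs = 0.5 * (probs + shifted)
    return probs  # probs[w] = P(2*W+ == w)


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25):
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped, ties get mid-ranks.  For n <= 25 the
    p-value comes from the exact null distribution of the signed-rank sum
    (computed over the realized mid-ranks); above that, a normal
    approximation with tie correction is used.
    Returns (W_plus, p_two_sided, n_nonzero).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        probs = _signed_rank_exact_cdf(ranks2)
        w2 = int(round(2 * w_plus))
        p_low = probs[:w2 + 1].sum()
        p_high = probs[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return w_plus, float(p), n


def spearman(x, y, alternative: str = "two-sided"):
    """Spearman rho (Pearson on mid-ranks) with t-approximation p-value.

    ``alternative`` is "two-sided", "greater" (rho > 0) or "less".
    Returns (rho, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need paired samples of length >= 4")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0 if alternative != "two-sided" else 0.0
        return rho, p, n
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    if alternative == "two-sided":
        p = 2 * t_dist.sf(abs(t), n - 2)
    elif alternative == "greater":
        p = t_dist.sf(t, n - 2)
    elif alternative == "less":
        p = t_dist.cdf(t, n - 2)
    else:
        raise ValueError("alternative must be two-sided/greater/less")
    return rho, float(p), n


def jzs_bf01_ttest(t: float, n: int,
                   prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """JZS (Cauchy-prior) Bayes factor for the null in a paired/one-sample design."""
    if not np.isfinite(t):
        raise ValueError("non-finite t statistic")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    r = prior_scale
    sqrt_n = np.sqrt(n)

    def integrand(theta):
        delta = r * np.tan(theta)
        jac = r / np.cos(theta) ** 2
        return nct.pdf(t, df, delta * sqrt_n) * cauchy.pdf(delta, 0.0, r) * jac

    num, _ = integrate.quad(integrand, -np.pi / 2, np.pi / 2,
                            epsabs=1e-8, epsrel=1e-10, limit=400)
    bf10 = num / t_dist.pdf(t, df)
    return BayesFactorResult(bf01=float(1.0 / bf10), t=float(t), n=int(n),
                             prior_scale=float(r))


def jzs_bf01_correlation(rho: float, n: int) -> float:
    """Approximate Jeffreys-type Bayes factor for a zero correlation.

    Applies the Jeffreys marginal likelihood
    ``L(rho_pop) ~ (1 - rho_pop^2)^((n-1)/2) / (1 - rho_pop * r)^(n - 3/2)``
    with a uniform prior on (-1, 1) to the observed rank correlation
    treated as a Pearson r.  Explicitly approximate: intended for
    descriptive reporting, not for matching any particular toolbox.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")

    def lik(p):
        return (1 - p ** 2) ** ((n - 1) / 2.0) / (1 - p * rho) ** (n - 1.5)

    num, _ = integrate.quad(lambda p: 0.5 * lik(p), -1, 1, epsabs=1e-10)
    return float(lik(0.0) / num)


def _ols_slope_se(X, y):
    """OLS coefficients and standard errors (X includes the intercept)."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def mediate(x, m, y, n_boot: int = 10000, seed: int = 0) -> MediationResult:
    """Single-mediator linear mediation with Sobel z and bootstrap CI.

    Paths: a (m ~ x), b and c' (y ~ x + m), c (y ~ x); indirect effect a*b;
    z is the Sobel statistic; the CI is a seeded percentile bootstrap over
    participants of the indirect effect.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(m) != n or len(y) != n or n < 10:
        raise ValueError("need equal-length triples, n >= 10")
    one = np.ones(n)
    Xa = np.column_stack([one, x])
    Xb = np.column_stack([one, x, m])
    if np.linalg.matrix_rank(Xb) < 3:
        raise ValueError("collinear predictors")
    beta_a, se_a_ = _ols_slope_se(Xa, m)
    a, se_a = beta_a[1], se_a_[1]
    beta_b, se_b_ = _ols_slope_se(Xb, y)
    c_prime, b = beta_b[1], beta_b[2]
    se_b = se_b_[2]
    beta_c, _ = _ols_slope_se(Xa, y)
    c_total = beta_c[1]
    z = (a * b) / np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    # closed-form per-resample regressions (vectorized over bootstrap draws)
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    a_b = (xc * mc).sum(axis=1) / (xc * xc).sum(axis=1)
    sxx = (xc * xc).sum(axis=1)
    smm = (mc * mc).sum(axis=1)
    sxm = (xc * mc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    det = sxx * smm - sxm ** 2
    b_b = (sxx * smy - sxm * sxy) / det
    ab = a_b * b_b
    lo, hi = np.percentile(ab, [2.5, 97.5])
    return MediationResult(a=float(a), b=float(b), c_total=float(c_total),
                           c_prime=float(c_prime), indirect_ab=float(a * b),
                           z=float(z), p_sobel=float(2 * norm.sf(abs(z))),
                           boot_ci=(float(lo), float(hi)),
                           n_boot=int(n_boot), seed=int(seed), n=n)


def mixed_model(y, fixed_design, group_labels, coef_names=None,
                reml: bool = True):
    """Random-intercept mixed model with fixed covariates (shared machinery).

    Thin wrapper over :func:`selfrag.prep.fit_lmm`; the returned fit exposes
    ``wald(name)`` for tests on individual coefficients.
    """
    from .prep import fit_lmm
    return fit_lmm(y, fixed_design, group_labels, coef_names=coef_names,
                   reml=reml)
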