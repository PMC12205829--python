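"""Trait-baseline residualization and questionnaire scoring.

Some traits are rated systematically higher than others (being "nice" beats
being "aggressive" on a 1-9 likability scale), and different conditions hold
different trait subsets.  Before any clustering, ratings are therefore
residualized against a random-intercept model grouped by trait,

    rating ~ 1 + (1 | trait),

fitted by REML over friend- and self-ratings from all conditions pooled.
The residual of a rated trial is ``rating - grand_mean - BLUP(trait)``; what
remains is person-specific evaluation relative to the trait's baseline.

The REML machinery is written as a one-dimensional profile likelihood over
the variance ratio ``lambda = var_between / var_within`` (coarse log-grid
bracket plus bounded Brent refinement, tolerance <= 1e-8 on the ratio).
For a random-intercept model every quantity reduces to group sums, so each
profile evaluation is O(N).  The same solver, with arbitrary fixed-effect
design matrices, backs the physiology and inference modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .ingest import (CONDITIONS, CONTROL_STATEMENTS, ILLUSION_STATEMENTS,
                     filter_rated)

_LAM_MAX = 1e8


class DegenerateFitWarning(UserWarning):
    """Variance component collapsed to (numerical) zero."""


@dataclass
class LmmFit:
    """Random-intercept linear mixed model fit (REML or ML)."""

    beta: np.ndarray
    se_beta: np.ndarray
    coef_names: list
    var_between: float
    var_within: float
    lam: float
    loglik: float
    group_labels: list
    group_effects_: np.ndarray      # BLUPs, aligned with group_labels
    reml: bool
    degenerate: bool = False

    @property
    def group_effects(self) -> dict:
        return dict(zip(self.group_labels, self.group_effects_.tolist()))

    def wald(self, name: str):
        """(estimate, se, z, two-sided p) for one fixed-effect coefficient."""
        from scipy.stats import norm
        i = self.coef_names.index(name)
        z = self.beta[i] / self.se_beta[i]
        return self.beta[i], self.se_beta[i], z, 2 * norm.sf(abs(z))


@dataclass
class RandomInterceptFit:
    """Intercept-only random-intercept model (the residualization model)."""

    grand_mean: float
    group_effects: dict
    var_between: float
    var_within: float
    log_restricted_likelihood: float
    degenerate: bool = False

    def residual(self, value: float, group) -> float:
        return value - self.grand_mean - self.group_effects.get(group, 0.0)


def _group_index(groups):
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    return labels.tolist(), idx


def _profile_pieces(y, X, idx, n_groups, lam):
    """Sufficient pieces of the GLS problem at variance ratio lam."""
    n_g = np.bincount(idx, minlength=n_groups).astype(float)
    a = lam / (1.0 + lam * n_g)                       # Woodbury per group
    Sy = np.bincount(idx, weights=y, minlength=n_groups)
    Sx = np.column_stack([np.bincount(idx, weights=X[:, j], minlength=n_groups)
                          for j in range(X.shape[1])])
    XtVX = X.T @ X - (Sx * a[:, None]).T @ Sx
    XtVy = X.T @ y - Sx.T @ (a * Sy)
    ytVy = y @ y - a @ (Sy ** 2)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = float(ytVy - beta @ XtVy)
    logdetV = float(np.log1p(lam * n_g).sum())
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    return beta, rss, logdetV, logdetXtVX, XtVX, Sy, Sx, n_g, a


def _neg_loglik(y, X, idx, n_groups, lam, reml):
    n, p = X.shape
    beta, rss, logdetV, logdetXtVX, *_ = _profile_pieces(y, X, idx, n_groups, lam)
    dof = n - p if reml else n
    rss = max(rss, 1e-300)
    sigma2 = rss / dof
    ll = -0.5 * (dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV)
    if reml:
        ll -= 0.5 * (logdetXtVX - p * np.log(sigma2))
    return -ll


def fit_lmm(y, X, groups, coef_names=None, reml: bool = True) -> LmmFit:
    """Random-intercept LMM with arbitrary fixed-effect design.

    y : response vector; X : (n, p) design (include the intercept column);
    groups : group label per row (the random-intercept factor).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("design/response length mismatch")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    labels, idx = _group_index(groups)
    G = len(labels)
    if G < 2:
        raise ValueError("need >= 2 groups")
    coef_names = coef_names or [f"b{j}" for j in range(X.shape[1])]

    nll = lambda lam: _neg_loglik(y, X, idx, G, lam, reml)
    grid = np.concatenate([[0.0], np.logspace(-8, 8, 97)])
    vals = np.array([nll(l) for l in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)] if k + 1 < len(grid) else _LAM_MAX
    if hi <= lo:
        hi = lo + 1.0
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9 * (1.0 + hi)})
    lam = float(res.x) if res.fun <= vals[k] else float(grid[k])

    beta, rss, logdetV, logdetXtVX, XtVX, Sy, Sx, n_g, a = _profile_pieces(
        y, X, idx, G, lam)
    n, p = X.shape
    dof = n - p if reml else n
    sigma2 = max(rss, 0.0) / dof
    degenerate = False
    if sigma2 < 1e-12:
        degenerate = True
        warnings.warn("residual variance is numerically zero",
                      DegenerateFitWarning)
    var_between = lam * sigma2
    # BLUP_g = shrinkage * (mean GLS residual of group g)
    resid_sum = Sy - Sx @ beta
    with np.errstate(invalid="ignore"):
        blup = (lam * n_g / (1.0 + lam * n_g)) * (resid_sum / np.maximum(n_g, 1))
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    return LmmFit(beta=beta, se_beta=se, coef_names=list(coef_names),
                  var_between=float(var_between), var_within=float(sigma2),
                  lam=lam, loglik=float(-res.fun if res.fun <= vals[k] else -vals[k]),
                  group_labels=labels, group_effects_=blup, reml=reml,
                  degenerate=degenerate)


def fit_random_intercept(values, groups) -> RandomInterceptFit:
    """REML intercept-only random-intercept model (``value ~ 1 + (1|group)``)."""
    values = np.asarray(values, dtype=float)
    fit = fit_lmm(values, np.ones((len(values), 1)), groups,
                  coef_names=["intercept"])
    return RandomInterceptFit(grand_mean=float(fit.beta[0]),
                              group_effects=fit.group_effects,
                              var_between=fit.var_between,
                              var_within=fit.var_within,
                              log_restricted_likelihood=fit.loglik,
                              degenerate=fit.degenerate)


def residualize_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Attach trait-baseline residuals to every rated row.

    One pooled model over all rows — both targets, all conditions — grouped
    by trait; timeout rows carry no residual and are dropped (their count is
    recorded on the returned frame's ``attrs``).
    """
    rated = filter_rated(ratings)
    n_dropped = len(ratings) - len(rated)
    if rated["trait_id"].nunique() < 2:
        raise ValueError("need ratings of at least 2 distinct traits")
    fit = fit_random_intercept(rated["rating"].astype(float).to_numpy(),
                               rated["trait_id"].to_numpy())
    blup = rated["trait_id"].map(fit.group_effects)
    out = rated.copy()
    out["residual"] = rated["rating"].astype(float) - fit.grand_mean - blup
    out.attrs["n_timeout_dropped"] = n_dropped
    out.attrs["fit"] = fit
    return out


def illusion_scores(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Illusion score = mean(I1..I3) - mean(C1..C4) per participant x condition.

    L1 is excluded.  Cells missing any scored statement get NaN (flagged,
    never imputed).
    """
    q = questionnaires
    wide = q.pivot_table(index=["participant_id", "condition"],
                         columns="statement_id", values="rating",
                         aggfunc="first")
    need = list(ILLUSION_STATEMENTS) + list(CONTROL_STATEMENTS)
    for st in need:
        if st not in wide.columns:
            wide[st] = np.nan
    score = (wide[list(ILLUSION_STATEMENTS)].mean(axis=1, skipna=False)
             - wide[list(CONTROL_STATEMENTS)].mean(axis=1, skipna=False))
    out = score.rename("illusion_score").reset_index()
    return out


def ownership_reduction(questionnaires: pd.DataFrame) -> pd.Series:
    """I1(syncSelf) - I1(asyncSelf) per participant (bodily-disownership index)."""
    q = questionnaires
    i1 = q[q["statement_id"] == "I1"].pivot_table(
        index="participant_id", columns="condition", values="rating",
        aggfunc="first")
    for cond in ("syncSelf", "asyncSelf"):
        if cond not in i1.columns or i1[cond].isna().any():
            missing = (i1.index[i1[cond].isna()].tolist()
                       if cond in i1.columns else i1.index.tolist())
            raise ValueError(f"I1 missing in {cond} for {missing[:3]}")
    return (i1["syncSelf"] - i1["asyncSelf"]).rename("ownership_reduction")
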