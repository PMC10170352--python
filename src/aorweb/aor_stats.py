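"""Abundance-occupancy relationship (AOR) models and companions.

The central model is a binomial logistic regression of site occupancy —
supplied as (occupied, not-occupied) count pairs — on log mean site
abundance, with dispersal ability and/or niche breadth as categorical
terms, optionally interacting with the slope.  Around it: Gaussian and
Poisson fits for the abundance contrasts, random-intercept mixed models
(island as grouping factor, Laplace-approximate likelihood), AICc model
selection, per-category subset fits with McFadden pseudo-R², and a 2x2
chi-squared association test.

Dummy coding uses a stated reference level per category, so the
full-interaction model's reference-level intercept and slope equal the
subset fit of the reference level, and the non-reference level equals
reference + main effect (+ interaction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import expit, gammaln
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "ModelSpec",
    "GLMResult",
    "build_design",
    "fit_glm",
    "fit_mixed",
    "subset_fits",
    "mcfadden_r2",
    "aicc",
    "aicc_table",
    "chi_sq_2x2",
    "SeparationWarning",
]


class SeparationWarning(UserWarning):
    """Quasi-perfect separation detected in a binomial fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model.

    ``response``: column name for gaussian/poisson, or a
    ``(successes, trials)`` column pair for binomial.
    ``covariate``: continuous predictor column (already transformed,
    e.g. log abundance); ``categories``: zero or more categorical
    columns, dummy-coded against ``reference`` levels; ``interaction``
    adds covariate x category terms.  ``grouping`` requests a
    random-intercept mixed model on that factor.
    """

    response: str | tuple[str, str]
    family: str  # gaussian | poisson | binomial
    covariate: str | None = None
    categories: tuple[str, ...] = ()
    interaction: bool = False
    grouping: str | None = None
    reference: Mapping[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not (
            isinstance(self.response, tuple) and len(self.response) == 2
        ):
            raise ValueError(
                "binomial response must be a (successes, trials) column pair"
            )

    @property
    def label(self) -> str:
        return self.name or "+".join(
            ([self.covariate] if self.covariate else [])
            + list(self.categories)
            + (["interaction"] if self.interaction else [])
        )


@dataclass
class GLMResult:
    """Coefficient table and fit summary for one model."""

    spec: ModelSpec
    table: pd.DataFrame  # index term; columns estimate, se, z, p
    loglik: float
    loglik_null: float
    k: int  # number of estimated parameters
    n: int
    aic: float
    aicc: float
    converged: bool = True
    separation: bool = False
    variance_components: dict[str, float] = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.table["estimate"]


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, covariate, category dummies and
    optional covariate x dummy interactions (treatment coding)."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    if spec.covariate is not None:
        cols.append(data[spec.covariate].to_numpy(float))
        names.append(spec.covariate)
    for cat in spec.categories:
        levels = sorted(data[cat].astype(str).unique())
        ref = spec.reference.get(cat, levels[0])
        if ref not in levels:
            raise ValueError(f"reference {ref!r} not a level of {cat!r}")
        for lev in levels:
            if lev == ref:
                continue
            dummy = (data[cat].astype(str) == lev).to_numpy(float)
            cols.append(dummy)
            names.append(f"{cat}[{lev}]")
            if spec.interaction and spec.covariate is not None:
                cols.append(dummy * data[spec.covariate].to_numpy(float))
                names.append(f"{spec.covariate}:{cat}[{lev}]")
    return np.column_stack(cols), names


def _endog(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if spec.family == "binomial":
        succ = data[spec.response[0]].to_numpy(float)
        trials = data[spec.response[1]].to_numpy(float)
        if np.any(succ > trials) or np.any(trials <= 0):
            raise ValueError("binomial needs 0 <= successes <= trials, trials > 0")
        return np.column_stack([succ, trials - succ])
    return data[spec.response].to_numpy(float)


_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "binomial": sm.families.Binomial,
}


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> GLMResult:
    """Maximum-likelihood GLM fit (IRLS via statsmodels).

    Complete cases only; rows with NA in any used column are dropped.
    Binomial/Poisson report Wald z p-values, Gaussian reports t.
    Quasi-perfect separation in binomial fits is flagged (and warned),
    never silently returned as converged estimates.
    """
    used = [c for c in _used_columns(spec) if c in data.columns]
    data = data.dropna(subset=used)
    X, names = build_design(data, spec)
    n = len(data)
    if n <= X.shape[1]:
        raise ValueError(f"n={n} too small for {X.shape[1]} parameters")
    y = _endog(data, spec)
    fam = _FAMILIES[spec.family]()
    model = sm.GLM(y, X, family=fam)
    res = model.fit()
    null = sm.GLM(y, np.ones((n, 1)), family=fam).fit()

    use_t = spec.family == "gaussian"
    stat = res.params / res.bse
    if use_t:
        p = 2 * scipy.stats.t.sf(np.abs(stat), df=n - X.shape[1])
    else:
        p = 2 * scipy.stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "z": stat, "p": p}, index=names
    )
    # scale parameter counts for gaussian AIC(c), matching common usage
    k = X.shape[1] + (1 if spec.family == "gaussian" else 0)
    separation = False
    if spec.family == "binomial":
        mu = res.fittedvalues
        if np.any(np.abs(res.params) > 25) or np.any(
            (mu < 1e-10) | (mu > 1 - 1e-10)
        ):
            separation = True
            warnings.warn(
                f"possible separation in model {spec.label!r}", SeparationWarning
            )
    return GLMResult(
        spec=spec,
        table=table,
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        k=k,
        n=n,
        aic=-2.0 * float(res.llf) + 2.0 * k,
        aicc=aicc(float(res.llf), k, n),
        converged=bool(res.converged),
        separation=separation,
    )


def _used_columns(spec: ModelSpec) -> list[str]:
    cols = list(spec.categories)
    if spec.covariate:
        cols.append(spec.covariate)
    if isinstance(spec.response, tuple):
        cols.extend(spec.response)
    else:
        cols.append(spec.response)
    if spec.grouping:
        cols.append(spec.grouping)
    return cols


# ---------------------------------------------------------------------------
# Random-intercept mixed models, Laplace approximation
# ---------------------------------------------------------------------------


def _loglik_terms(family: str, eta: np.ndarray, y: np.ndarray, log_sigma_e: float):
    """Per-observation log-likelihood and its first/second derivatives
    with respect to the linear predictor (canonical links)."""
    if family == "binomial":
        s, f = y[:, 0], y[:, 1]
        m = s + f
        mu = expit(eta)
        ll = (
            s * eta
            - m * np.logaddexp(0.0, eta)
            + gammaln(m + 1)
            - gammaln(s + 1)
            - gammaln(f + 1)
        )
        return ll, s - m * mu, -m * mu * (1 - mu)
    if family == "poisson":
        lam = np.exp(eta)
        ll = y * eta - lam - gammaln(y + 1)
        return ll, y - lam, -lam
    # gaussian, identity link, residual sd exp(log_sigma_e)
    s2 = np.exp(2 * log_sigma_e)
    resid = y - eta
    ll = -0.5 * np.log(2 * np.pi * s2) - 0.5 * resid**2 / s2
    return ll, resid / s2, np.full_like(eta, -1.0 / s2)


def _laplace_nll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    family: str,
    u_work: np.ndarray,
) -> float:
    p = X.shape[1]
    beta = theta[:p]
    log_sigma_u = theta[p]
    log_sigma_e = theta[p + 1] if family == "gaussian" else 0.0
    s2u = np.exp(2 * log_sigma_u)
    xb = X @ beta
    u = u_work
    # Newton iterations for the joint mode of the random intercepts; the
    # per-group objective is concave for all three families
    for _ in range(50):
        eta = xb + u[g]
        _, d1, d2 = _loglik_terms(family, eta, y, log_sigma_e)
        grad = np.bincount(g, weights=d1, minlength=n_groups) - u / s2u
        hess = np.bincount(g, weights=d2, minlength=n_groups) - 1.0 / s2u
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    u_work[:] = u  # warm start for the next outer iteration
    eta = xb + u[g]
    ll_obs, _, d2 = _loglik_terms(family, eta, y, log_sigma_e)
    f = (
        np.bincount(g, weights=ll_obs, minlength=n_groups)
        - 0.5 * u**2 / s2u
        - 0.5 * np.log(2 * np.pi * s2u)
    )
    neg_fpp = -(np.bincount(g, weights=d2, minlength=n_groups) - 1.0 / s2u)
    ll = np.sum(f + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(neg_fpp))
    return -ll


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> GLMResult:
    """Random-intercept GLMM on ``spec.grouping``, Laplace likelihood.

    The fixed-effect table mirrors :func:`fit_glm`; the random-intercept
    standard deviation is reported in ``variance_components['sigma_u']``.
    A fit collapsing onto the boundary (sigma_u -> 0) is still valid —
    it reduces to the plain GLM — but a singular fit is flagged via
    ``converged``.
    """
    if spec.grouping is None:
        raise ValueError("spec.grouping required for a mixed model")
    used = [c for c in _used_columns(spec) if c in data.columns]
    data = data.dropna(subset=used)
    groups, g = np.unique(data[spec.grouping].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("grouping factor needs >= 2 levels")
    X, names = build_design(data, spec)
    y = _endog(data, spec)
    n = len(data)

    start = fit_glm(
        ModelSpec(
            response=spec.response,
            family=spec.family,
            covariate=spec.covariate,
            categories=spec.categories,
            interaction=spec.interaction,
            reference=spec.reference,
        ),
        data,
    )
    p = X.shape[1]
    theta0 = np.concatenate(
        [
            start.params.to_numpy(),
            [np.log(0.5)],
            [np.log(np.std(y - X @ start.params.to_numpy()) + 1e-6)]
            if spec.family == "gaussian"
            else [],
        ]
    )
    u_work = np.zeros(len(groups))
    args = (X, y, g, len(groups), spec.family, u_work)
    opt = scipy.optimize.minimize(
        _laplace_nll, theta0, args=args, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    theta = opt.x
    loglik = -float(opt.fun)
    hess = approx_hess1(theta, _laplace_nll, args=args)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov)[:p], 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    beta = theta[:p]
    stat = beta / se
    pvals = 2 * scipy.stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {"estimate": beta, "se": se, "z": stat, "p": pvals}, index=names
    )
    sigma_u = float(np.exp(theta[p]))
    k = p + 1 + (1 if spec.family == "gaussian" else 0)
    vc = {"sigma_u": sigma_u}
    if spec.family == "gaussian":
        vc["sigma_e"] = float(np.exp(theta[p + 1]))
    return GLMResult(
        spec=spec,
        table=table,
        loglik=loglik,
        loglik_null=np.nan,
        k=k,
        n=n,
        aic=-2 * loglik + 2 * k,
        aicc=aicc(loglik, k, n),
        converged=bool(opt.success) and sigma_u > 1e-6,
        variance_components=vc,
    )


# ---------------------------------------------------------------------------
# Derived reports
# ---------------------------------------------------------------------------


def mcfadden_r2(result: GLMResult) -> float:
    """McFadden pseudo-R²: 1 - loglik(model)/loglik(null)."""
    if result.loglik_null == 0 or not np.isfinite(result.loglik_null):
        raise ValueError("null log-likelihood unavailable or zero")
    return 1.0 - result.loglik / result.loglik_null


def subset_fits(
    data: pd.DataFrame,
    category: str,
    response: tuple[str, str],
    covariate: str,
    family: str = "binomial",
    min_rows: int = 3,
) -> pd.DataFrame:
    """Per-level AOR fits: occupancy ~ covariate within each category level.

    Returns one row per level with intercept, slope, their p-values and
    McFadden R².  Levels with fewer than ``min_rows`` species are
    flagged (NaN estimates) rather than fitted.
    """
    rows = []
    for level, grp in data.groupby(category):
        if len(grp) < min_rows:
            rows.append((level, len(grp), *[np.nan] * 5))
            continue
        res = fit_glm(
            ModelSpec(response=response, family=family, covariate=covariate),
            grp,
        )
        rows.append(
            (
                level,
                len(grp),
                res.table.loc["intercept", "estimate"],
                res.table.loc["intercept", "p"],
                res.table.loc[covariate, "estimate"],
                res.table.loc[covariate, "p"],
                mcfadden_r2(res),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            category,
            "n",
            "intercept",
            "p_intercept",
            "slope",
            "p_slope",
            "mcfadden_r2",
        ],
    ).set_index(category)


def aicc_table(results: Sequence[GLMResult]) -> pd.DataFrame:
    """Rank models by AICc; ΔAICc relative to the best (Δ = 0)."""
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise ValueError(f"models fitted on differing n: {sorted(ns)}")
    rows = [
        (r.spec.label, r.k, float(r.loglik), r.aic, r.aicc) for r in results
    ]
    out = pd.DataFrame(
        rows, columns=["model", "k", "loglik", "aic", "aicc"]
    ).set_index("model")
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    return out.sort_values("delta_aicc")


def chi_sq_2x2(
    table: np.ndarray | Sequence[Sequence[int]], yates: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-squared test of association on a 2x2 table.

    Yates continuity correction is on by default (the R ``chisq.test``
    convention for 2x2 tables).  Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    stat, p, df, _ = scipy.stats.chi2_contingency(t, correction=yates)
    return float(stat), int(df), float(p)
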