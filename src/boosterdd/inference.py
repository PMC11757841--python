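"""Country-nested random-intercept logistic regression and summaries.

The model: y_ic ~ Bernoulli(logit⁻¹(x_icᵀβ + u_c)), u_c ~ Normal(0, σ²),
one Gaussian intercept per country.  The marginal likelihood integrates the
country effects out; because the model has a single scalar random effect the
integral factorizes into one-dimensional integrals per country, which are
evaluated by adaptive Gauss–Hermite quadrature centred at each country's
conditional mode (one node recovers the Laplace approximation).  β and σ are
maximized jointly by quasi-Newton with σ bounded at zero, so a data set with
no between-country variance collapses to ordinary logistic regression.

Fixed effects are reported as b, SE, z, two-sided p, OR = exp(b), and Wald
95% CIs exp(b ± 1.96·SE); the random part as the intercept variance with its
SD (= √variance).  A likelihood-ratio test against the random-intercept-only
null isolates the fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .errors import DegenerateInputError, DomainError, FitError, UsageError

__all__ = [
    "ModelFit",
    "LrtResult",
    "scale_predictors",
    "build_design",
    "glmm_loglik",
    "fit_glmm",
    "lrt",
    "group_curves",
]

_Z95 = 1.96  # Wald multiplier for 95% intervals


@dataclass(frozen=True)
class ModelFit:
    """Fitted random-intercept logistic model."""

    params: pd.DataFrame  # index: term; columns b, se, z, p, or, ci_low, ci_high
    intercept_variance: float
    intercept_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    fixed_terms: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = ["Fixed effects", self.params.round(3).to_string()]
        lines += [
            "Random effects",
            f"  intercept variance (group): {self.intercept_variance:.3f}"
            f"  (SD {self.intercept_sd:.3f})",
            f"log-likelihood {self.loglik:.2f}   n={self.n_obs} groups={self.n_groups}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


def scale_predictors(table: pd.DataFrame, which: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """z-score the named columns (sample sd, n−1); others untouched.

    The applied centres/scales are recorded in ``result.attrs['scaling']``
    for reporting.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in which:
        v = pd.to_numeric(out[col], errors="raise").astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateInputError(f"column {col!r} has zero variance; cannot scale")
        scaling[col] = (float(v.mean()), float(sd))
        out[col] = (v - v.mean()) / sd
    out.attrs["scaling"] = scaling
    return out


def build_design(table: pd.DataFrame, predictors: list[str] | tuple[str, ...],
                 scale: list[str] | tuple[str, ...] = ()) -> np.ndarray:
    """Design matrix with a leading intercept column; ``scale`` columns z-scored."""
    df = scale_predictors(table, [c for c in scale if c in predictors]) if scale else table
    cols = [np.ones(len(df))]
    cols += [pd.to_numeric(df[p], errors="raise").to_numpy(dtype=float) for p in predictors]
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------

def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _conditional_modes(eta0, y, gidx, n_groups, sigma2, max_iter=100, tol=1e-10):
    """Per-group posterior modes of u via damped Newton (concave objective)."""
    u = np.zeros(n_groups)
    for _ in range(max_iter):
        mu = special.expit(eta0 + u[gidx])
        grad = np.bincount(gidx, weights=y - mu, minlength=n_groups) - u / sigma2
        if np.max(np.abs(grad)) < tol:
            break
        w = np.bincount(gidx, weights=mu * (1.0 - mu), minlength=n_groups) + 1.0 / sigma2
        u += np.clip(grad / w, -4.0, 4.0)
    mu = special.expit(eta0 + u[gidx])
    w = np.bincount(gidx, weights=mu * (1.0 - mu), minlength=n_groups) + 1.0 / sigma2
    return u, 1.0 / np.sqrt(w)


def glmm_loglik(y, X, gidx, beta, sigma, n_groups: int | None = None,
                n_nodes: int = 15) -> float:
    """Marginal log-likelihood at (β, σ) by adaptive Gauss–Hermite quadrature.

    ``gidx`` holds 0-based group codes.  At σ = 0 the integral degenerates and
    the ordinary Bernoulli log-likelihood is returned, making the surface
    continuous down to the boundary.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    gidx = np.asarray(gidx)
    if n_groups is None:
        n_groups = int(gidx.max()) + 1
    beta = np.asarray(beta, dtype=float)
    eta0 = X @ beta
    if sigma < 1e-8:
        return float(np.sum(_bernoulli_loglik(eta0, y)))
    sigma2 = sigma * sigma
    u_hat, s_hat = _conditional_modes(eta0, y, gidx, n_groups, sigma2)
    t, w = hermgauss(n_nodes)
    logs = np.empty((n_nodes, n_groups))
    sqrt2 = np.sqrt(2.0)
    for k in range(n_nodes):
        uk = u_hat + sqrt2 * s_hat * t[k]
        li = np.bincount(gidx, weights=_bernoulli_loglik(eta0 + uk[gidx], y),
                         minlength=n_groups)
        li += -0.5 * np.log(2.0 * np.pi * sigma2) - uk * uk / (2.0 * sigma2)
        logs[k] = np.log(w[k]) + t[k] * t[k] + li
    per_group = special.logsumexp(logs, axis=0) + 0.5 * np.log(2.0) + np.log(s_hat)
    return float(per_group.sum())


def _parse_formula(formula: str) -> tuple[str, list[str]]:
    lhs, _, rhs = formula.partition("~")
    outcome = lhs.strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip() not in ("", "1")]
    if not outcome:
        raise UsageError(f"cannot parse formula {formula!r}")
    return outcome, terms


def fit_glmm(
    table: pd.DataFrame,
    formula: str | None = None,
    *,
    outcome: str | None = None,
    predictors: list[str] | tuple[str, ...] = (),
    group: str = "country",
    scale: list[str] | tuple[str, ...] = (),
    n_nodes: int = 15,
    maxiter: int = 500,
) -> ModelFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    ``formula`` ("y ~ a + b") or ``outcome``/``predictors`` select the terms;
    ``scale`` names predictors to z-score first (constants recorded in the
    result).  Rows with a missing value in any model column are dropped
    listwise.  Raises :class:`FitError` on non-convergence and warns when a
    coefficient diverges (quasi-separation).
    """
    if formula is not None:
        outcome, predictors = _parse_formula(formula)
    if outcome is None:
        raise UsageError("provide a formula or an outcome name")
    predictors = list(predictors)

    cols = [outcome, group, *predictors]
    data = table[cols].dropna()
    if len(data) == 0:
        raise DomainError("no complete rows to fit on")
    y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError(f"outcome {outcome!r} must be binary 0/1")
    codes, levels = pd.factorize(data[group], sort=True)
    n_groups = len(levels)
    if n_groups < 2:
        raise DomainError("need at least 2 groups for a random intercept")

    scale = [c for c in scale if c in predictors]
    scaled = scale_predictors(data, scale) if scale else data
    X = np.column_stack(
        [np.ones(len(scaled))]
        + [pd.to_numeric(scaled[p]).to_numpy(dtype=float) for p in predictors]
    )
    p = X.shape[1]

    # starting values: plain logistic for β, a mid-range σ
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    x0 = np.r_[beta0, 0.3]

    def negll(params: np.ndarray) -> float:
        return -glmm_loglik(y, X, codes, params[:p], params[p], n_groups, n_nodes)

    res = optimize.minimize(
        negll, x0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(0.0, 10.0)],
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise FitError(f"GLMM optimisation produced a non-finite likelihood: {res.message}")
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise FitError(f"GLMM optimisation failed: {res.message} (nit={res.nit})")
    beta_hat, sigma_hat = res.x[:p], float(res.x[p])

    if np.any(np.abs(beta_hat) > 15):
        flagged = [t for t, b in zip(["intercept", *predictors], beta_hat) if abs(b) > 15]
        warnings.warn(f"possible separation; diverging coefficients: {flagged}", stacklevel=2)

    # Wald SEs from the β-block Hessian at the estimated variance
    def negll_beta(b: np.ndarray) -> float:
        return -glmm_loglik(y, X, codes, b, sigma_hat, n_groups, n_nodes)

    hess = approx_hess1(beta_hat, negll_beta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise FitError(f"singular Hessian at the optimum: {e}") from e
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {
            "b": beta_hat,
            "se": se,
            "z": z,
            "p": pvals,
            "or": np.exp(beta_hat),
            "ci_low": np.exp(beta_hat - _Z95 * se),
            "ci_high": np.exp(beta_hat + _Z95 * se),
        },
        index=pd.Index(["intercept", *predictors], name="term"),
    )
    return ModelFit(
        params=params,
        intercept_variance=sigma_hat**2,
        intercept_sd=sigma_hat,
        loglik=-float(res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        fixed_terms=tuple(["intercept", *predictors]),
        diagnostics={
            "method": "adaptive Gauss-Hermite quadrature",
            "n_nodes": n_nodes,
            "converged": bool(res.success),
            "n_iter": int(res.nit),
            "message": str(res.message),
        },
        scaling=dict(getattr(scaled, "attrs", {}).get("scaling", {})),
    )


def lrt(full: ModelFit, null: ModelFit) -> LrtResult:
    """Likelihood-ratio test of nested fits on identical rows."""
    if full.n_obs != null.n_obs or full.n_groups != null.n_groups:
        raise UsageError(
            f"models fitted on different data: n={full.n_obs}/{null.n_obs}, "
            f"groups={full.n_groups}/{null.n_groups}"
        )
    if not set(null.fixed_terms) <= set(full.fixed_terms):
        raise UsageError("null model terms are not a subset of the full model terms")
    df = len(full.fixed_terms) - len(null.fixed_terms)
    statistic = 2.0 * (full.loglik - null.loglik)
    if statistic < -1e-6:
        raise UsageError(
            f"full-model likelihood below the null ({statistic:.3g}); models are not nested"
        )
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else (1.0 if statistic == 0 else 0.0)
    return LrtResult(statistic=float(statistic), df=df, p=p)


def group_curves(profiles, outcomes) -> pd.DataFrame:
    """Mean indifference point and SE at each delay, split by outcome group.

    Returns a long table with columns group, delay_days, mean, se, n — the
    numeric content of the willing/unwilling discounting-curve figure.
    """
    outcomes = np.asarray(outcomes)
    profiles = list(profiles)
    if len(profiles) != len(outcomes):
        raise UsageError("each profile must be paired with one outcome")
    rows = []
    for g in np.unique(outcomes):
        members = [p for p, o in zip(profiles, outcomes) if o == g]
        if not members:
            raise DomainError(f"group {g!r} is empty")
        sv = np.array([m.subjective_values for m in members])
        days = members[0].days
        mean = sv.mean(axis=0)
        se = sv.std(axis=0, ddof=1) / np.sqrt(len(members)) if len(members) > 1 else np.zeros(len(days))
        for d, m, s in zip(days, mean, se):
            rows.append((g, d, m, s, len(members)))
    return pd.DataFrame(rows, columns=["group", "delay_days", "mean", "se", "n"])
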