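"""Mixed-effects Poisson and logistic regression via the Laplace approximation.

Latent structure is a per-subject Gaussian intercept plus, for the Poisson
family, an optional observation-level random effect (OLRE) absorbing
overdispersion.  Because observations are nested within subjects, the joint
Hessian over (subject intercept, per-observation effects) is block-arrowhead
per subject, so the inner Newton mode-finding and the Laplace log-determinant
are both O(n) per iteration.  Variance components are optimized on the log
scale; standard errors come from the inverse observed information of the
Laplace objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .diagnostics import standardize_predictors, vif

__all__ = [
    "ModelSpec",
    "MixedFit",
    "build_design",
    "fit_glmm",
    "wald_table",
    "lrt_equal_coefficients",
    "parametric_bootstrap_ci",
    "marginal_loglik",
]

FAMILIES = ("poisson-log", "binomial-logit")

_ETA_MAX = 30.0


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    fixed: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    family: str = "poisson-log"
    subject_col: str = "subject_id"
    subject_intercept: bool = True
    olre: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "interactions", tuple(tuple(i) for i in self.interactions))
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.olre and self.family != "poisson-log":
            raise ValueError("the observation-level random effect is only used with the Poisson family")
        for a, b in self.interactions:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(f"interaction ({a}, {b}) references undeclared main effects")

    def term_names(self) -> list[str]:
        return ["intercept"] + list(self.fixed) + [f"{a}:{b}" for a, b in self.interactions]


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    names: list[str]
    groups: np.ndarray
    n_subjects: int
    scaling: dict[str, tuple[float, float]]
    subject_ids: np.ndarray


@dataclass
class MixedFit:
    spec: ModelSpec
    design: Design
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau: float | None
    sigma_olre: float | None
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int
    vif: pd.Series
    message: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


# ---------------------------------------------------------------------------
# family kernels
# ---------------------------------------------------------------------------


def _loglik_obs(family: str, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    if family == "poisson-log":
        return y * eta - np.exp(eta) - gammaln(y + 1.0)
    return y * eta - np.logaddexp(0.0, eta)


def _mu_w(family: str, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    if family == "poisson-log":
        mu = np.exp(eta)
        return mu, mu
    mu = expit(eta)
    return mu, mu * (1.0 - mu)


# ---------------------------------------------------------------------------
# inner Laplace machinery
# ---------------------------------------------------------------------------


def _inner_mode(
    family: str,
    xb: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_subjects: int,
    tau2: float | None,
    sigma2: float | None,
    u0: np.ndarray | None = None,
    e0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 50,
):
    """Damped Newton mode of the penalized log-likelihood over the latents.

    Returns (u, e, penalized ll at mode, log-det of the negative Hessian).
    Exploits the per-subject arrowhead structure of the Hessian.
    """
    n = y.size
    has_u = tau2 is not None
    has_e = sigma2 is not None
    u = np.zeros(n_subjects) if u0 is None else u0.copy()
    e = np.zeros(n) if e0 is None else e0.copy()

    def pen_ll(u, e):
        eta = xb + (u[groups] if has_u else 0.0) + (e if has_e else 0.0)
        val = _loglik_obs(family, eta, y).sum()
        if has_u:
            val -= 0.5 * np.dot(u, u) / tau2
        if has_e:
            val -= 0.5 * np.dot(e, e) / sigma2
        return val, eta

    f_cur, eta = pen_ll(u, e)
    for _ in range(maxiter):
        mu, w = _mu_w(family, eta)
        resid = y - mu
        if has_u:
            grad_u = np.bincount(groups, resid, minlength=n_subjects) - u / tau2
        if has_e:
            grad_e = resid - e / sigma2

        if has_u and has_e:
            d = w + 1.0 / sigma2
            a = np.bincount(groups, w, minlength=n_subjects) + 1.0 / tau2
            schur = a - np.bincount(groups, w * w / d, minlength=n_subjects)
            rhs_u = grad_u - np.bincount(groups, w * grad_e / d, minlength=n_subjects)
            du = rhs_u / schur
            de = (grad_e - w * du[groups]) / d
            gmax = max(np.abs(grad_u).max(initial=0), np.abs(grad_e).max(initial=0))
        elif has_u:
            a = np.bincount(groups, w, minlength=n_subjects) + 1.0 / tau2
            du, de = grad_u / a, None
            gmax = np.abs(grad_u).max(initial=0)
        elif has_e:
            d = w + 1.0 / sigma2
            du, de = None, grad_e / d
            gmax = np.abs(grad_e).max(initial=0)
        else:
            break

        if gmax < tol:
            break
        step = 1.0
        accepted = False
        for _ in range(30):
            u_new = u + step * du if has_u else u
            e_new = e + step * de if has_e else e
            f_new, eta_new = pen_ll(u_new, e_new)
            if f_new >= f_cur - 1e-13:
                improved = f_new - f_cur > 1e-12 * (1.0 + abs(f_cur))
                u, e, f_cur, eta = u_new, e_new, f_new, eta_new
                accepted = improved
                break
            step *= 0.5
        if not accepted:  # stagnated at numerical precision
            break

    _, w = _mu_w(family, eta)
    if has_u and has_e:
        d = w + 1.0 / sigma2
        a = np.bincount(groups, w, minlength=n_subjects) + 1.0 / tau2
        schur = a - np.bincount(groups, w * w / d, minlength=n_subjects)
        logdet = np.log(d).sum() + np.log(schur).sum()
    elif has_u:
        a = np.bincount(groups, w, minlength=n_subjects) + 1.0 / tau2
        logdet = np.log(a).sum()
    elif has_e:
        d = w + 1.0 / sigma2
        logdet = np.log(d).sum()
    else:
        logdet = 0.0
    return u, e, f_cur, logdet


def marginal_loglik(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    tau: float | None = None,
    sigma_olre: float | None = None,
    state: dict | None = None,
) -> float:
    """Laplace-approximate marginal log-likelihood at fixed parameters."""
    n = y.size
    n_subjects = int(groups.max()) + 1 if groups.size else 0
    xb = X @ beta
    tau2 = tau**2 if tau is not None else None
    sigma2 = sigma_olre**2 if sigma_olre is not None else None
    if tau2 is None and sigma2 is None:
        return float(_loglik_obs(family, xb, y).sum())
    u0 = state.get("u") if state else None
    e0 = state.get("e") if state else None
    u, e, pen, logdet = _inner_mode(
        family, xb, y, groups, n_subjects, tau2, sigma2, u0, e0
    )
    if state is not None:
        state["u"], state["e"] = u, e
    val = pen - 0.5 * logdet
    if tau2 is not None:
        val -= 0.5 * n_subjects * np.log(tau2)
    if sigma2 is not None:
        val -= 0.5 * n * np.log(sigma2)
    return float(val)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    required = [spec.outcome, *spec.fixed]
    if spec.subject_intercept:
        required.append(spec.subject_col)
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise KeyError(f"data is missing required columns: {missing}")
    work = data
    scaling: dict[str, tuple[float, float]] = {}
    if spec.standardize:
        work, scaling = standardize_predictors(data, list(spec.fixed))
    cols = [np.ones(len(work))]
    for name in spec.fixed:
        cols.append(work[name].to_numpy(dtype=float))
    for a, b in spec.interactions:
        cols.append(work[a].to_numpy(dtype=float) * work[b].to_numpy(dtype=float))
    X = np.column_stack(cols)
    y = work[spec.outcome].to_numpy(dtype=float)
    if spec.family == "binomial-logit" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcome must be 0/1")
    if spec.family == "poisson-log" and (np.any(y < 0) or np.any(y != np.rint(y))):
        raise ValueError("poisson outcome must be a nonnegative integer count")
    if spec.subject_intercept:
        subject_ids, groups = np.unique(work[spec.subject_col].to_numpy(), return_inverse=True)
        if subject_ids.size < 2:
            raise ValueError("need >= 2 subjects to fit a subject random intercept")
    else:
        subject_ids, groups = np.array([]), np.zeros(len(work), dtype=int)
    return Design(
        X=X,
        y=y,
        names=spec.term_names(),
        groups=groups,
        n_subjects=int(subject_ids.size),
        scaling=scaling,
        subject_ids=subject_ids,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_SD_BOUNDS = (-7.0, 3.0)


def _fit_matrices(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_subjects: int,
    use_subject: bool,
    use_olre: bool,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> dict:
    n, p = X.shape
    n_var = int(use_subject) + int(use_olre)
    if start is None:
        beta0 = np.zeros(p)
        if family == "poisson-log":
            beta0[0] = np.log(max(y.mean(), 1e-3))
        else:
            pbar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
            beta0[0] = np.log(pbar / (1 - pbar))
        theta0 = np.concatenate([beta0, np.full(n_var, np.log(0.3))])
    else:
        theta0 = np.asarray(start, dtype=float).copy()

    def negll(theta):
        # cold inner start keeps the objective a pure function of theta,
        # which finite-difference gradients require
        beta = theta[:p]
        k = p
        tau = np.exp(theta[k]) if use_subject else None
        k += int(use_subject)
        sigma = np.exp(theta[k]) if use_olre else None
        return -marginal_loglik(family, X, y, groups, beta, tau, sigma)

    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS] * n_var
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
    )
    if not res.success:
        # restart once from the stalled point, then fall back to a
        # gradient-free polish before giving up
        res2 = optimize.minimize(
            negll, res.x, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            res3 = optimize.minimize(
                negll, res.x, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 5000},
            )
            if res3.fun <= res.fun + 1e-9:
                res = res3
    theta = res.x
    beta = theta[:p]
    tau = float(np.exp(theta[p])) if use_subject else None
    sigma = float(np.exp(theta[p + int(use_subject)])) if use_olre else None
    boundary = bool(
        (use_subject and theta[p] <= _LOG_SD_BOUNDS[0] + 1e-6)
        or (use_olre and theta[p + int(use_subject)] <= _LOG_SD_BOUNDS[0] + 1e-6)
    )

    se = np.full(p, np.nan)
    se_note = ""
    if compute_se:
        h = _num_hessian(negll, theta)

        def _try_invert(mat):
            try:
                dvar = np.diag(np.linalg.inv(mat))[:p]
            except np.linalg.LinAlgError:
                return None
            if np.all(np.isfinite(dvar)) and np.all(dvar > 0):
                return np.sqrt(dvar)
            return None

        got = _try_invert(h)
        if got is None and h.shape[0] > p:
            # information singular in a variance direction (boundary):
            # report SEs conditional on the variance components
            got = _try_invert(h[:p, :p])
            se_note = "; SEs conditional on variance components (boundary)"
        if got is not None:
            se = got
        else:
            se_note = "; SE computation failed (singular information)"
    return {
        "beta": beta,
        "se": se,
        "tau": tau,
        "sigma": sigma,
        "loglik": float(-res.fun),
        "converged": bool(res.success),
        "boundary": boundary,
        "n_iter": int(res.nit),
        "theta": theta,
        "message": str(res.message) + se_note,
    }


def _num_hessian(fun, x, eps: float = 1e-4):
    x = np.asarray(x, dtype=float)
    m = x.size
    h = np.empty((m, m))
    steps = eps * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = steps[i]
        h[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / steps[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return h


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, compute_se: bool = True) -> MixedFit:
    """Fit the mixed model by maximizing the Laplace marginal likelihood.

    Raises on non-convergence rather than returning a silent estimate;
    near-zero variance components are surfaced through the ``boundary`` flag.
    """
    design = build_design(spec, data)
    raw = _fit_matrices(
        spec.family,
        design.X,
        design.y,
        design.groups,
        design.n_subjects,
        use_subject=spec.subject_intercept,
        use_olre=spec.olre,
        compute_se=compute_se,
    )
    if not raw["converged"]:
        raise RuntimeError(
            f"GLMM fit did not converge: {raw['message']} "
            f"(loglik trace end {raw['loglik']:.6f}, {raw['n_iter']} iterations)"
        )
    fit = MixedFit(
        spec=spec,
        design=design,
        names=design.names,
        beta=raw["beta"],
        se=raw["se"],
        tau=raw["tau"],
        sigma_olre=raw["sigma"],
        loglik=raw["loglik"],
        converged=raw["converged"],
        boundary=raw["boundary"],
        n_iter=raw["n_iter"],
        vif=vif(design.X, design.names),
        message=raw["message"],
        extras={"theta": raw["theta"]},
    )
    return fit


def wald_table(fit: MixedFit) -> pd.DataFrame:
    """Coefficient table with Wald z and two-sided normal p-values."""
    if not fit.converged:
        raise ValueError("wald_table requires a converged fit")
    tab = pd.DataFrame(
        {
            "term": fit.names,
            "b": fit.beta,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p,
        }
    )
    tab.loc[tab["se"] == 0, ["z", "p"]] = np.nan
    return tab


def lrt_equal_coefficients(
    spec: ModelSpec, data: pd.DataFrame, term_a: str, term_b: str
):
    """Likelihood-ratio test of equality between two fixed-effect coefficients.

    The restricted model replaces the two design columns by their sum (which
    constrains the coefficients to be equal); the statistic is twice the
    log-likelihood difference on 1 df.
    """
    from .stattests import TestResult

    design = build_design(spec, data)
    names = design.names
    for t in (term_a, term_b):
        if t not in names:
            raise ValueError(f"term {t!r} not in model terms {names}")
    ia, ib = names.index(term_a), names.index(term_b)

    full = _fit_matrices(
        spec.family, design.X, design.y, design.groups, design.n_subjects,
        spec.subject_intercept, spec.olre, compute_se=False,
    )
    Xr = np.delete(design.X, ib, axis=1).copy()
    ia_r = ia if ia < ib else ia - 1
    Xr[:, ia_r] = design.X[:, ia] + design.X[:, ib]
    start_r = np.delete(full["theta"], ib)
    restricted = _fit_matrices(
        spec.family, Xr, design.y, design.groups, design.n_subjects,
        spec.subject_intercept, spec.olre, start=start_r, compute_se=False,
    )
    delta = full["loglik"] - restricted["loglik"]
    if delta < -1e-4:
        raise RuntimeError(
            "restricted model log-likelihood exceeds the full model's "
            f"({restricted['loglik']:.6f} > {full['loglik']:.6f}); convergence failure"
        )
    statistic = max(0.0, 2.0 * delta)
    return TestResult(
        name=f"lrt_equal[{term_a}={term_b}]",
        statistic=float(statistic),
        p_value=float(stats.chi2.sf(statistic, df=1)),
        method="lrt",
        df=1,
    )


def _simulate_outcome(fit: MixedFit, rng: np.random.Generator) -> np.ndarray:
    design = fit.design
    eta = design.X @ fit.beta
    if fit.tau is not None and fit.spec.subject_intercept:
        u = rng.normal(0.0, fit.tau, size=design.n_subjects)
        eta = eta + u[design.groups]
    if fit.sigma_olre is not None and fit.spec.olre:
        eta = eta + rng.normal(0.0, fit.sigma_olre, size=design.y.size)
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    if fit.spec.family == "poisson-log":
        return rng.poisson(np.exp(eta)).astype(float)
    return (rng.random(design.y.size) < expit(eta)).astype(float)


def parametric_bootstrap_ci(
    fit: MixedFit,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Percentile bootstrap CIs by simulating from the fitted model and refitting."""
    rng = np.random.default_rng(seed)
    design = fit.design
    draws = np.full((n_boot, len(fit.beta)), np.nan)
    failures = 0
    for b in range(n_boot):
        ystar = _simulate_outcome(fit, rng)
        try:
            raw = _fit_matrices(
                fit.spec.family, design.X, ystar, design.groups, design.n_subjects,
                fit.spec.subject_intercept, fit.spec.olre,
                start=fit.extras["theta"], compute_se=False,
            )
            if not raw["converged"]:
                raise RuntimeError("bootstrap refit failed to converge")
            draws[b] = raw["beta"]
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed (> {max_failure_rate:.0%})"
        )
    ok = draws[~np.isnan(draws).any(axis=1)]
    lo = np.percentile(ok, 100 * alpha / 2, axis=0)
    hi = np.percentile(ok, 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame({"term": fit.names, "ci_low": lo, "ci_high": hi})
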