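"""Random-intercept GLMMs by adaptive Gauss-Hermite quadrature.

Two families are supported:

* ``logistic`` — Bernoulli outcome, logit link;
* ``negbin`` — NB2 counts (variance mu + alpha*mu^2), log link, optional
  log person-years offset; the dispersion alpha is estimated jointly.

The marginal likelihood integrates a single Gaussian random intercept per
group (county). For each group the integrand is recentred at its
conditional mode with curvature-matched scaling before Gauss-Hermite
quadrature, so a modest number of nodes (default 15) is accurate; the
quadrature is validated elsewhere against dense numerical integration.

With ``fix_sigma=0`` the model degenerates to an ordinary GLM, fitted here
by Newton-Raphson (logistic) or analytic-gradient quasi-Newton (negbin) —
no external fitting library is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, gammaln, logsumexp

FAMILIES = ("logistic", "negbin")

_ETA_CLIP = 30.0

_HERMGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _HERMGAUSS_CACHE:
        _HERMGAUSS_CACHE[n] = np.polynomial.hermite.hermgauss(n)
    return _HERMGAUSS_CACHE[n]


# ---------------------------------------------------------------------------
# model specification / fit containers


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family, outcome, exposure term(s), adjustment set."""

    family: str
    outcome: str
    exposure: str | tuple[str, ...] | None
    covariates: tuple[str, ...] = ()
    group: str = "county"
    offset: str | None = None  # person-years column; log taken internally
    n_quad: int = 15
    fix_sigma: float | None = None
    spline: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.offset is not None and self.family != "negbin":
            raise ValueError("offset is only supported for the negbin family")
        if self.spline and self.exposure_terms and len(self.exposure_terms) > 1:
            raise ValueError("spline exposure must be a single continuous term")

    @property
    def exposure_terms(self) -> tuple[str, ...]:
        if self.exposure is None:
            return ()
        if isinstance(self.exposure, str):
            return (self.exposure,)
        return tuple(self.exposure)


@dataclass
class ModelFit:
    spec: ModelSpec
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma_u: float
    alpha: float | None
    loglik: float
    converged: bool
    n: int
    n_groups: int
    effects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def measure(self) -> str:
        return "OR" if self.spec.family == "logistic" else "RR"

    @property
    def effect_estimate(self) -> float | None:
        if len(self.effects) == 0:
            return None
        return float(self.effects["estimate"].iloc[0])

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    data: pd.DataFrame, terms: tuple[str, ...], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix with reference-coded categoricals.

    Categorical (object/category) columns are dummy-coded against the first
    level in lexicographic order; booleans and numerics pass through.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(data)
    if add_intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
    for t in terms:
        s = data[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, s.dropna().unique()))
            vals = s.astype(str).to_numpy()
            for lvl in levels[1:]:  # first level is the reference
                cols.append((vals == lvl).astype(float))
                names.append(f"{t}[{lvl}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(t)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    from scipy.linalg import qr as _pivoted_qr

    _, R, piv = _pivoted_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# family log-likelihood terms and derivatives in eta


def _ll_terms(y: np.ndarray, eta: np.ndarray, family: str, alpha: float | None):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "logistic":
        return y * eta - np.logaddexp(0.0, eta)
    mu = np.exp(eta)
    a = alpha
    return (
        gammaln(y + 1.0 / a)
        - gammaln(1.0 / a)
        - gammaln(y + 1.0)
        + y * np.log(a)
        + y * eta
        - (y + 1.0 / a) * np.log1p(a * mu)
    )


def _ll_derivs(y: np.ndarray, eta: np.ndarray, family: str, alpha: float | None):
    """First and second derivatives of the loglik terms w.r.t. eta."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "logistic":
        p = expit(eta)
        return y - p, -p * (1.0 - p)
    mu = np.exp(eta)
    a = alpha
    denom = 1.0 + a * mu
    d1 = (y - mu) / denom
    d2 = -mu * (1.0 + a * y) / denom**2
    return d1, d2


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature


def _conditional_modes(
    f: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    n_groups: int,
    sigma: float,
    family: str,
    alpha: float | None,
    max_iter: int = 50,
    tol: float = 1e-10,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group mode and curvature of loglik(u) + log N(u; 0, sigma^2).

    The integrand is log-concave in u for both families, so undamped Newton
    with a step clip converges quickly; ``u0`` warm-starts the search.
    """
    inv_s2 = 1.0 / sigma**2
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    for _ in range(max_iter):
        eta = f + u[group]
        d1, d2 = _ll_derivs(y, eta, family, alpha)
        g = np.bincount(group, weights=d1, minlength=n_groups) - u * inv_s2
        h = np.bincount(group, weights=d2, minlength=n_groups) - inv_s2
        step = np.clip(-g / h, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(g)) < tol:
            break
    eta = f + u[group]
    _, d2 = _ll_derivs(y, eta, family, alpha)
    curv = -(np.bincount(group, weights=d2, minlength=n_groups) - inv_s2)
    return u, curv


def marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    group: np.ndarray,
    family: str = "logistic",
    alpha: float | None = None,
    offset: np.ndarray | None = None,
    n_quad: int = 15,
    u0: np.ndarray | None = None,
    return_modes: bool = False,
):
    """Marginal log-likelihood, integrating the group intercepts by AGQ.

    Exposed so the quadrature can be checked against brute-force numerical
    integration at arbitrary parameter values. ``u0`` warm-starts the
    conditional-mode search (an optimisation detail: the modes are always
    converged to tolerance regardless of the start).
    """
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    n_groups = int(group.max()) + 1
    f = X @ beta
    if offset is not None:
        f = f + offset
    if sigma == 0.0:
        ll0 = float(np.sum(_ll_terms(y, f, family, alpha)))
        return (ll0, np.zeros(n_groups)) if return_modes else ll0
    modes, curv = _conditional_modes(f, y, group, n_groups, sigma, family, alpha, u0=u0)
    z, w = _hermgauss(n_quad)
    scale = np.sqrt(2.0 / curv)  # per group
    log_prior_const = -0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    u_nodes = modes[:, None] + scale[:, None] * z[None, :]  # (G, K)
    eta = f[:, None] + u_nodes[group]  # (n, K)
    terms = _ll_terms(y[:, None], eta, family, alpha)
    ll_gk = np.empty((n_groups, n_quad))
    for k in range(n_quad):
        ll_gk[:, k] = np.bincount(group, weights=terms[:, k], minlength=n_groups)
    prior = log_prior_const - u_nodes**2 / (2.0 * sigma**2)
    A = np.log(w)[None, :] + z[None, :] ** 2 + ll_gk + prior
    ll = float(np.sum(logsumexp(A, axis=1) + np.log(scale)))
    return (ll, modes) if return_modes else ll


# ---------------------------------------------------------------------------
# GLM (sigma = 0) fitting paths


def _logistic_newton(y, X, tol=1e-12, max_iter=100):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        grad = X.T @ (y - p)
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None]) + 1e-12 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            break
    ll = float(np.sum(_ll_terms(y, X @ beta, "logistic", None)))
    H = X.T @ (X * (expit(X @ beta) * (1 - expit(X @ beta)))[:, None])
    return beta, H, ll


def _negbin_glm_negll_grad(theta, y, X, offset):
    p = X.shape[1]
    beta, log_alpha = theta[:p], theta[p]
    a = np.exp(log_alpha)
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = np.sum(_ll_terms(y, eta, "negbin", a))
    d1 = (y - mu) / (1.0 + a * mu)
    g_beta = X.T @ d1
    dll_da = (
        -special.polygamma(0, y + 1.0 / a) / a**2
        + special.polygamma(0, 1.0 / a) / a**2
        + y / a
        + np.log1p(a * mu) / a**2
        - (y + 1.0 / a) * mu / (1.0 + a * mu)
    )
    g_la = float(np.sum(dll_da)) * a  # chain rule through log-alpha
    return -ll, -np.concatenate([g_beta, [g_la]])


# ---------------------------------------------------------------------------
# numerical Hessian (central differences)


def _numeric_hessian(fun, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    p = len(x)
    H = np.empty((p, p))
    hs = eps * (1.0 + np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


# ---------------------------------------------------------------------------
# the main fitting entry point


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    terms = spec.exposure_terms + tuple(spec.covariates)
    X, names = build_design(data, terms)
    y = data[spec.outcome].to_numpy(dtype=float)
    codes, levels = pd.factorize(data[spec.group], sort=True)
    if spec.fix_sigma is None and len(levels) < 2:
        raise ValueError("random intercept requires >= 2 groups")
    offset = None
    if spec.offset is not None:
        py = data[spec.offset].to_numpy(dtype=float)
        if np.any(py <= 0):
            raise ValueError("offset person-years must be positive")
        offset = np.log(py)
    return y, X, names, codes.astype(np.int64), len(levels), offset


def fit_glmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximise the AGQ marginal likelihood; Wald inference from the
    observed-information inverse.

    Non-convergence and separation are flagged (``converged=False``), never
    silently replaced by a fallback fit.
    """
    y, X_raw, names, group, n_groups, offset = _prepare(spec, data)
    n, p = X_raw.shape
    family = spec.family
    estimate_alpha = family == "negbin"

    # fit on column-standardized covariates (exact reparameterization;
    # estimates are transformed back) so badly scaled exposures such as
    # raw IDW sums do not stall the optimizer
    col_scale = np.ones(p)
    for j in range(1, p):
        sd = X_raw[:, j].std()
        if sd > 0:
            col_scale[j] = sd
    X = X_raw / col_scale

    if spec.fix_sigma is not None and spec.fix_sigma == 0.0 and family == "logistic":
        beta_s, H, ll = _logistic_newton(y, X)
        vcov = np.linalg.pinv(H) / np.outer(col_scale, col_scale)
        beta = beta_s / col_scale
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))
        fit = ModelFit(
            spec, names, beta, se, vcov, 0.0, None, ll,
            converged=bool(np.all(np.abs(beta_s) < 30)), n=n, n_groups=n_groups,
        )
        fit.effects = _effects_frame(fit)
        return fit

    # starting values from an unpenalized no-random-effect fit
    if family == "logistic":
        beta0, _, _ = _logistic_newton(y, X, tol=1e-6, max_iter=25)
    else:
        # Poisson IRLS start
        beta0 = np.zeros(p)
        off = offset if offset is not None else 0.0
        for _ in range(25):
            eta = np.clip(X @ beta0 + off, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            Wd = mu
            z = eta - off + (y - mu) / np.maximum(mu, 1e-8)
            A = X.T @ (X * Wd[:, None]) + 1e-8 * np.eye(p)
            beta0 = np.linalg.solve(A, X.T @ (Wd * z))

    if spec.fix_sigma is not None and spec.fix_sigma == 0.0:
        # negbin GLM: analytic-gradient quasi-Newton over (beta, log alpha)
        x0 = np.concatenate([beta0, [np.log(0.5)]])
        res = optimize.minimize(
            _negbin_glm_negll_grad, x0, args=(y, X, offset), jac=True,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(np.log(1e-8), np.log(1e3))],
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        polish = optimize.minimize(
            _negbin_glm_negll_grad, res.x, args=(y, X, offset), jac=True,
            method="BFGS", options={"maxiter": 200, "gtol": 1e-10},
        )
        if polish.fun <= res.fun:
            res = polish
        beta = res.x[:p] / col_scale
        alpha = float(np.exp(res.x[p]))
        nll = lambda t: _negbin_glm_negll_grad(t, y, X, offset)[0]  # noqa: E731
        H = _numeric_hessian(nll, res.x)
        sc = np.concatenate([col_scale, [1.0]])
        vcov = np.linalg.pinv(H) / np.outer(sc, sc)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))[:p]
        fit = ModelFit(
            spec, names, beta, se, vcov[:p, :p], 0.0, alpha, -res.fun,
            converged=bool(res.success), n=n, n_groups=n_groups,
        )
        fit.effects = _effects_frame(fit)
        return fit

    fix_sigma = spec.fix_sigma
    free_sigma = fix_sigma is None

    def unpack(theta):
        beta = theta[:p]
        k = p
        if free_sigma:
            sigma = float(np.exp(theta[k]))
            k += 1
        else:
            sigma = float(fix_sigma)
        alpha = float(np.exp(theta[k])) if estimate_alpha else None
        return beta, sigma, alpha

    u_cache = {"u": None}

    def neg_ll(theta):
        beta, sigma, alpha = unpack(theta)
        ll, modes = marginal_loglik(
            beta, sigma, y, X, group, family, alpha, offset, spec.n_quad,
            u0=u_cache["u"], return_modes=True,
        )
        u_cache["u"] = modes
        return -ll

    x0 = list(beta0)
    bounds: list[tuple] = [(None, None)] * p
    if free_sigma:
        x0.append(np.log(0.3))
        bounds.append((np.log(1e-4), np.log(20.0)))
    if estimate_alpha:
        x0.append(np.log(0.5))
        bounds.append((np.log(1e-8), np.log(1e3)))
    res = optimize.minimize(
        neg_ll, np.array(x0), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta_s, sigma, alpha = unpack(res.x)
    H = _numeric_hessian(neg_ll, res.x)
    sc = np.concatenate([col_scale, np.ones(len(res.x) - p)])
    vcov_full = np.linalg.pinv(H) / np.outer(sc, sc)
    beta = beta_s / col_scale
    d = np.diag(vcov_full)
    ok = bool(res.success) and np.all(np.isfinite(d[:p])) and np.all(d[:p] > 0)
    se = np.sqrt(np.clip(d[:p], 0.0, np.inf))
    if np.any(np.abs(beta_s) > 30):
        ok = False  # likely separation
    fit = ModelFit(
        spec, names, beta, se, vcov_full[:p, :p], sigma, alpha, -res.fun,
        converged=ok, n=n, n_groups=n_groups,
    )
    fit.effects = _effects_frame(fit)
    return fit


def _effects_frame(fit: ModelFit, zcrit: float = 1.959963984540054) -> pd.DataFrame:
    rows = []
    for term in fit.spec.exposure_terms:
        # a categorical exposure expands to several columns; report each
        matching = [nm for nm in fit.names if nm == term or nm.startswith(f"{term}[")]
        for nm in matching:
            j = fit.names.index(nm)
            b, s = float(fit.beta[j]), float(fit.se[j])

            def _exp(v):  # keep degenerate fits finite in the output
                return float(np.exp(np.clip(v, -700.0, 700.0)))

            rows.append(
                {
                    "term": nm,
                    "measure": fit.measure,
                    "estimate": _exp(b),
                    "lower": _exp(b - zcrit * s),
                    "upper": _exp(b + zcrit * s),
                    "beta": b,
                    "se": s,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting and residuals


def effect_table(fits: list[ModelFit]) -> pd.DataFrame:
    """One row per (outcome, exposure term) with estimate and 95% Wald CI.

    Empty input yields an empty table with the full header. Values survive
    a round trip through delimited text at 6 significant digits.
    """
    cols = [
        "outcome", "exposure", "family", "measure",
        "estimate", "lower", "upper", "beta", "se",
        "sigma_u", "alpha", "converged", "n",
    ]
    rows = []
    for fit in fits:
        for _, eff in fit.effects.iterrows():
            rows.append(
                {
                    "outcome": fit.spec.outcome,
                    "exposure": eff["term"],
                    "family": fit.spec.family,
                    "measure": eff["measure"],
                    "estimate": eff["estimate"],
                    "lower": eff["lower"],
                    "upper": eff["upper"],
                    "beta": eff["beta"],
                    "se": eff["se"],
                    "sigma_u": fit.sigma_u,
                    "alpha": fit.alpha if fit.alpha is not None else np.nan,
                    "converged": fit.converged,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def deviance_residuals(fit: ModelFit, data: pd.DataFrame) -> np.ndarray:
    """Per-observation deviance residuals, conditional on the estimated
    group modes (empirical-Bayes intercepts)."""
    y, X, _, group, n_groups, offset = _prepare(fit.spec, data)
    f = X @ fit.beta
    if offset is not None:
        f = f + offset
    if fit.sigma_u > 0:
        modes, _ = _conditional_modes(
            f, y, group, n_groups, fit.sigma_u, fit.spec.family, fit.alpha
        )
        eta = f + modes[group]
    else:
        eta = f
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if fit.spec.family == "logistic":
        mu = expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        dev = 2.0 * (t1 + t0)
    else:
        a = fit.alpha
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
        dev = 2.0 * (t1 - t2)
    return np.sign(y - mu) * np.sqrt(np.clip(dev, 0.0, np.inf))
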