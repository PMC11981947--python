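"""Random-intercept generalized linear models for connectivity data.

Two response families cover the anatomical measurements analysed here:

- ``poisson`` for synapse counts N_syn (optionally with a log L_d offset, in
  which case the model describes the synapse conversion rate N_syn / L_d);
- ``tweedie`` for the co-travel distance L_d, a non-negative continuous
  variable with a point mass at zero. A Tweedie variable with index
  xi in (1, 2) is a Poisson mixture of gammas: N ~ Pois(lambda) proximity
  stretches whose lengths are iid Gamma, summed.

The model is  g(E[y_ij]) = x_ij' beta + u_g(ij) (+ offset),  g = log, with
u_g ~ N(0, sigma^2) random intercepts for a grouping factor (presynaptic
neuron within projection-by-proofread stratum in the intended application).
Fitting is penalized IRLS jointly in (beta, u) with the classic
Breslow-Clayton variance update sigma^2 <- (u'u + tr(H_uu^-1)) / q, i.e. a
Laplace-type approximation adequate for the moderate group counts used here.
The Tweedie index xi is profiled over a grid by exact series likelihood.

This is deliberately not a general mixed-model engine: one random-intercept
term, log link, two families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

XI_GRID = np.round(np.arange(1.1, 1.95, 0.1), 2)  # profiled Tweedie index values


# ---------------------------------------------------------------------------
# Tweedie / compound Poisson-gamma primitives
# ---------------------------------------------------------------------------

def tweedie_to_cpg(mu: np.ndarray, phi: float, xi: float):
    """Convert (mean, dispersion, index) to compound Poisson-gamma parameters.

    Returns (poisson rate lambda, gamma shape a, gamma scale s); the gamma
    mean is a * s.
    """
    mu = np.asarray(mu, float)
    lam = mu ** (2.0 - xi) / (phi * (2.0 - xi))
    shape = (2.0 - xi) / (xi - 1.0)
    scale = phi * (xi - 1.0) * mu ** (xi - 1.0)
    return lam, shape, scale


def sample_compound_poisson_gamma(
    lam: float | np.ndarray,
    gamma_mean: float,
    gamma_shape: float,
    rng: np.random.Generator,
    size=None,
) -> np.ndarray:
    """Draw sums of N ~ Pois(lam) iid Gamma(shape, mean/shape) variables.

    The sample mean converges to lam * gamma_mean.
    """
    n = rng.poisson(lam, size=size)
    n = np.atleast_1d(n)
    out = np.zeros(n.shape, float)
    pos = n > 0
    # sum of k iid Gamma(a, s) is Gamma(k a, s)
    scale = np.broadcast_to(np.asarray(gamma_mean, float) / gamma_shape, n.shape)
    out[pos] = rng.gamma(n[pos] * gamma_shape, scale[pos])
    return out


def tweedie_logpdf(y: np.ndarray, mu: np.ndarray, phi: float, xi: float,
                   max_terms: int = 400) -> np.ndarray:
    """Exact series log-density of the Tweedie distribution, 1 < xi < 2.

    Uses the compound Poisson-gamma representation; the series over the
    latent Poisson count is evaluated around its dominant term.
    """
    y = np.asarray(y, float)
    mu = np.broadcast_to(np.asarray(mu, float), y.shape).copy()
    lam, a, s = tweedie_to_cpg(mu, phi, xi)
    out = np.empty(y.shape, float)
    zero = y == 0
    out[zero] = -lam[zero]
    pos = ~zero
    if pos.any():
        yp, lamp, sp = y[pos], lam[pos], s[pos]
        # dominant index of the series (Dunn & Smyth)
        jmax = np.clip(yp ** (2.0 - xi) / (phi * (2.0 - xi)), 1.0, None)
        hi = int(min(max(np.ceil(jmax.max() * 4 + 20), 30), max_terms))
        j = np.arange(1, hi + 1)[:, None]  # (terms, n_pos)
        logw = (
            j * np.log(lamp)[None, :]
            + j * a * (np.log(yp) - np.log(sp))[None, :]
            - gammaln(j * a)
            - gammaln(j + 1)
        )
        out[pos] = -lamp - yp / sp - np.log(yp) + logsumexp(logw, axis=0)
    return out


def tweedie_profile_phi(y, mu, xi, bracket=(1e-4, 1e4)) -> tuple[float, float]:
    """Maximum-likelihood dispersion for fixed mu and xi.

    Returns (phi_hat, loglik at phi_hat).
    """
    from scipy.optimize import minimize_scalar

    def nll(log_phi):
        return -float(np.sum(tweedie_logpdf(y, mu, np.exp(log_phi), xi)))

    res = minimize_scalar(
        nll, bounds=(np.log(bracket[0]), np.log(bracket[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x)), -float(res.fun)


# ---------------------------------------------------------------------------
# Penalized IRLS fitter
# ---------------------------------------------------------------------------

@dataclass
class GlmmResult:
    """A fitted random-intercept GLM."""

    family: str
    params: np.ndarray  # fixed-effect coefficients
    bse: np.ndarray  # their standard errors
    exog_names: list
    random_effects: np.ndarray  # BLUP-style group intercepts
    group_labels: list
    sigma2: float  # random-intercept variance
    phi: float  # dispersion (1 for Poisson)
    xi: float | None  # Tweedie index (None for Poisson)
    converged: bool
    n_obs: int
    loglik: float | None = None
    cov_params: np.ndarray | None = None
    n_iter: int = 0
    xi_profile: dict = field(default_factory=dict)  # xi -> loglik

    def predict(self, X: np.ndarray, groups=None, offset=None) -> np.ndarray:
        """Mean response; unknown/absent groups get a zero random effect."""
        eta = np.asarray(X, float) @ self.params
        if offset is not None:
            eta = eta + np.asarray(offset, float)
        if groups is not None:
            lut = {g: u for g, u in zip(self.group_labels, self.random_effects)}
            eta = eta + np.array([lut.get(g, 0.0) for g in groups])
        return np.exp(eta)


def _variance_power(family: str, xi: float | None) -> float:
    if family == "poisson":
        return 1.0
    if family == "tweedie":
        if xi is None:
            raise ValueError("tweedie family needs an index xi")
        return float(xi)
    raise ValueError(f"unsupported family {family!r}")


def _pirls(y, X, group_idx, q, var_power, offset, prior_weights, sigma2,
           max_iter=200, tol=1e-10):
    """Penalized IRLS for fixed random-effect variance.

    Returns beta, u, cov_beta(unit dispersion), H_uu diag info, n_iter.
    """
    n, p = X.shape
    w_prior = np.ones(n) if prior_weights is None else prior_weights
    off = np.zeros(n) if offset is None else offset

    # initialize on the data scale
    mu = np.clip(y + 0.5, 1e-8, None) if var_power != 1.0 else np.clip(y, 0.1, None) + 0.1
    eta = np.log(mu)
    beta = np.zeros(p)
    u = np.zeros(q)

    for it in range(max_iter):
        mu = np.exp(eta)
        mu = np.clip(mu, 1e-10, 1e10)
        # log link: d mu / d eta = mu; working weight w = mu^2 / V(mu)
        w = w_prior * mu ** (2.0 - var_power)
        z = (eta - off) + (y - mu) / mu  # working response (offset removed)

        XtW = X.T * w
        A11 = XtW @ X
        b1 = XtW @ z
        # group aggregations for the sparse indicator block
        swz = np.bincount(group_idx, weights=w * z, minlength=q)
        sw = np.bincount(group_idx, weights=w, minlength=q)
        A12 = np.zeros((p, q))
        for j in range(p):
            A12[j] = np.bincount(group_idx, weights=w * X[:, j], minlength=q)
        A = np.zeros((p + q, p + q))
        A[:p, :p] = A11
        A[:p, p:] = A12
        A[p:, :p] = A12.T
        A[p:, p:] = np.diag(sw + 1.0 / sigma2)
        b = np.concatenate([b1, swz])
        sol = np.linalg.solve(A, b)
        new_beta, new_u = sol[:p], sol[p:]
        new_eta = X @ new_beta + new_u[group_idx] + off
        step = max(np.max(np.abs(new_beta - beta)), np.max(np.abs(new_u - u)) if q else 0.0)
        beta, u, eta = new_beta, new_u, new_eta
        if step < tol:
            break
    Ainv = np.linalg.inv(A)
    return beta, u, eta, Ainv, it + 1


def fit_glmm(
    y,
    X,
    groups=None,
    family: str = "poisson",
    offset=None,
    exog_names=None,
    xi: float | None = None,
    xi_grid=None,
    prior_weights=None,
    max_outer: int = 50,
    tol: float = 1e-8,
) -> GlmmResult:
    """Fit a log-link GLM with optional random intercepts.

    Parameters
    ----------
    y, X : response and fixed-effect design (include the intercept column).
    groups : group label per row for the random intercept, or None for a
        plain GLM.
    family : "poisson" or "tweedie".
    offset : added to the linear predictor (e.g. log L_d for rate models).
    xi : fix the Tweedie index; when None it is profiled over ``xi_grid``
        (default 1.1 .. 1.9) by exact series likelihood.
    prior_weights : observation weights (used by the density formulation of
        the rate model).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if exog_names is None:
        exog_names = [f"x{j}" for j in range(p)]
    if groups is None:
        group_idx = np.zeros(n, int)
        q = 0
        labels = []
        # no random effects: emulate with a single group of infinite penalty
        group_idx = np.zeros(n, int)
        q = 1
        labels = ["_none_"]
        fixed_sigma2 = 1e-12
    else:
        labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
        labels = list(labels)
        q = len(labels)
        fixed_sigma2 = None
    offset = None if offset is None else np.asarray(offset, float)

    if family == "tweedie" and xi is None:
        grid = XI_GRID if xi_grid is None else np.asarray(xi_grid, float)
        best = None
        profile = {}
        for xi_k in grid:
            fit_k = fit_glmm(
                y, X, groups, family, offset, exog_names, xi=float(xi_k),
                prior_weights=prior_weights, max_outer=max_outer, tol=tol,
            )
            profile[float(xi_k)] = fit_k.loglik
            if best is None or fit_k.loglik > best.loglik:
                best = fit_k
        best.xi_profile = profile
        return best

    var_power = _variance_power(family, xi)
    sigma2 = 0.5 if fixed_sigma2 is None else fixed_sigma2
    beta = u = eta = Ainv = None
    n_iter = 0
    converged = False
    for outer in range(max_outer):
        beta, u, eta, Ainv, it = _pirls(
            y, X, group_idx, q, var_power, offset, prior_weights, sigma2
        )
        n_iter += it
        if fixed_sigma2 is not None:
            converged = True
            break
        # Laplace-type variance update
        H_uu_inv_diag = np.diag(Ainv)[p:]
        new_sigma2 = float((u @ u + H_uu_inv_diag.sum()) / q)
        new_sigma2 = max(new_sigma2, 1e-10)
        if abs(new_sigma2 - sigma2) < tol * max(sigma2, 1e-6):
            sigma2 = new_sigma2
            converged = True
            break
        sigma2 = new_sigma2

    mu = np.exp(eta)
    if family == "poisson":
        phi = 1.0
        from scipy.special import gammaln as _gl

        if prior_weights is None and np.allclose(y, np.round(y)):
            ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, None)) - mu - _gl(y + 1)))
        else:
            ll = None  # quasi-likelihood (weighted density formulation)
    else:
        phi, ll = tweedie_profile_phi(y, mu, var_power)

    cov = Ainv[:p, :p] * phi
    return GlmmResult(
        family=family,
        params=beta,
        bse=np.sqrt(np.clip(np.diag(cov), 0, None)),
        exog_names=list(exog_names),
        random_effects=u if fixed_sigma2 is None else np.zeros(0),
        group_labels=labels if fixed_sigma2 is None else [],
        sigma2=sigma2 if fixed_sigma2 is None else 0.0,
        phi=phi,
        xi=None if family == "poisson" else var_power,
        converged=converged,
        n_obs=n,
        loglik=ll,
        cov_params=cov,
        n_iter=n_iter,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (nan-safe passthrough)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
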