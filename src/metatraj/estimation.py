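"""Full-information maximum likelihood estimation and goodness of fit.

Each participant contributes the multivariate-normal log-density of whichever
observations they have, evaluated under the model-implied mean for their
covariate profile and the shared model-implied covariance restricted to the
observed positions.  Under a missing-at-random mechanism this yields
asymptotically unbiased estimates without imputation or case deletion.

Participants are grouped by missingness pattern so each pattern's covariance
sub-matrix is factorized once; the grouped value is identical to a naive
per-participant evaluation.

The likelihood is maximized by L-BFGS-B in an unconstrained packed parameter
space (log variances, log-diagonal Cholesky factors for covariance blocks).
Gradients are exact up to floating point: the derivative of the log-likelihood
with respect to the moment structure (mean maps and covariance) is available
in closed form per missingness pattern, and the Jacobian of the moment
structure with respect to the packed parameters is obtained by complex-step
differentiation of the (data-free, cheap) moment map.

Goodness of fit contrasts the structured model with two reference models
estimated on the same data: the unrestricted model (multivariate regression of
the outcomes on the covariates with unstructured residual covariance, fitted
by an EM algorithm) and an independence baseline (free means and variances,
zero covariances).  These yield the likelihood-ratio chi-square, SRMR and CFI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor as _cho_factor, cho_solve as _cho_solve

from .model import (
    ModelSpec,
    ParameterSet,
    default_parameters,
    default_spec,
    free_parameter_names,
    moment_maps,
    n_free_parameters,
    pack_parameters,
    unpack_parameters,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "FitIndices",
    "SaturatedResult",
    "BaselineResult",
    "JointMomentModel",
    "fiml_loglik",
    "fit",
    "fit_moment_model",
    "standard_errors",
    "saturated_fit",
    "baseline_fit",
    "fit_indices",
    "srmr_from_moments",
    "classify_srmr",
    "classify_cfi",
]

_LOG2PI = np.log(2.0 * np.pi)


class NonConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# missingness patterns and the grouped likelihood
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    obs: np.ndarray      # observed column indices
    Y: np.ndarray        # (n_p, k) observed values
    W: np.ndarray        # (n_p, q) covariates


@dataclass
class _Group:
    """Patterns sharing an observed-variable count, stacked for batched
    linear algebra."""

    obs: np.ndarray      # (m, k) observed indices per pattern
    Y: np.ndarray        # (N, k) member rows, pattern-contiguous
    W: np.ndarray        # (N, q)
    pid: np.ndarray      # (N,) pattern index within the group
    counts: np.ndarray   # (m,)
    offsets: np.ndarray  # (m,) reduceat offsets


class PatternSet:
    """Rows grouped by missingness pattern, with a batched compilation."""

    def __init__(self, patterns: list[_Pattern], p: int):
        self.patterns = patterns
        self.p = p
        self._groups = None

    def __len__(self):
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    @property
    def groups(self) -> list[_Group]:
        if self._groups is None:
            by_k: dict[int, list[_Pattern]] = {}
            for pat in self.patterns:
                by_k.setdefault(pat.obs.size, []).append(pat)
            groups = []
            for k, pats in sorted(by_k.items()):
                counts = np.array([pat.Y.shape[0] for pat in pats])
                groups.append(_Group(
                    obs=np.stack([pat.obs for pat in pats]),
                    Y=np.vstack([pat.Y for pat in pats]),
                    W=np.vstack([pat.W for pat in pats]),
                    pid=np.repeat(np.arange(len(pats)), counts),
                    counts=counts,
                    offsets=np.concatenate([[0], np.cumsum(counts)[:-1]]),
                ))
            self._groups = groups
        return self._groups


def prepare_patterns(Y: np.ndarray, W: np.ndarray) -> PatternSet:
    """Group rows of ``Y`` (NaN = missing) by missingness pattern."""
    Y = np.asarray(Y, float)
    W = np.asarray(W, float)
    if Y.ndim != 2 or W.ndim != 2 or Y.shape[0] != W.shape[0]:
        raise ValueError("Y and W must be 2-d with matching row counts")
    mask = np.isnan(Y)
    if np.any(mask.all(axis=1)):
        raise ValueError("every participant must have at least one observed value")
    keys, inverse = np.unique(mask, axis=0, return_inverse=True)
    patterns = []
    for g in range(keys.shape[0]):
        rows = np.flatnonzero(inverse == g)
        obs = np.flatnonzero(~keys[g])
        patterns.append(_Pattern(obs=obs, Y=Y[np.ix_(rows, obs)], W=W[rows]))
    return PatternSet(patterns, Y.shape[1])


def _pattern_loglik(M0, Mw, Sigma, pset: PatternSet, want_grad=False):
    """Observed-data log-likelihood and, optionally, its gradient with
    respect to the moment structure (M0, Mw, Sigma).

    Evaluates pattern groups in batched form; the value is identical to a
    naive per-participant evaluation with explicit sub-matrix extraction.
    """
    p = M0.shape[0]
    q = Mw.shape[1]
    ll = 0.0
    if want_grad:
        gM0 = np.zeros(p)
        gMw = np.zeros_like(Mw)
        gS = np.zeros((p, p))
    for grp in pset.groups:
        m, k = grp.obs.shape
        S = Sigma[grp.obs[:, :, None], grp.obs[:, None, :]]      # (m, k, k)
        try:
            C = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None, None) if want_grad else -np.inf
        logdet = 2.0 * np.log(np.einsum("gii->gi", C)).sum(axis=1)
        Sinv = np.linalg.inv(S)
        mu = M0[grp.obs][grp.pid]
        if q:
            mu = mu + np.einsum("nq,nkq->nk", grp.W, Mw[grp.obs][grp.pid])
        R = grp.Y - mu
        X = np.einsum("nij,nj->ni", Sinv[grp.pid], R)
        ll += -0.5 * (
            float(grp.counts @ (k * _LOG2PI + logdet)) + float(np.sum(R * X))
        )
        if want_grad:
            Xsum = np.add.reduceat(X, grp.offsets, axis=0)
            np.add.at(gM0, grp.obs, Xsum)
            if q:
                XW = np.add.reduceat(X[:, :, None] * grp.W[:, None, :],
                                     grp.offsets, axis=0)
                np.add.at(gMw, grp.obs, XW)
            Cmat = np.add.reduceat(X[:, :, None] * X[:, None, :],
                                   grp.offsets, axis=0)
            G = 0.5 * (Cmat - grp.counts[:, None, None] * Sinv)
            np.add.at(gS, (grp.obs[:, :, None], grp.obs[:, None, :]), G)
    if want_grad:
        return ll, gM0, gMw, gS
    return ll


# ---------------------------------------------------------------------------
# moment models
# ---------------------------------------------------------------------------

class MomentModel(Protocol):
    """Anything that maps a packed parameter vector to a moment structure.

    ``moments`` must accept a complex-valued vector (for complex-step
    differentiation) and return ``(M0, Mw, Sigma)`` in that dtype.
    """

    n_free: int

    def moments(self, theta: np.ndarray): ...


class JointMomentModel:
    """The joint metabolic growth model as a :class:`MomentModel`."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.n_free = n_free_parameters(spec)

    def moments(self, theta):
        return moment_maps(unpack_parameters(theta, self.spec), self.spec)

    def unpack(self, theta) -> ParameterSet:
        return unpack_parameters(theta, self.spec)


def _moment_jacobian(model: MomentModel, theta: np.ndarray):
    """Complex-step Jacobian of the stacked moment vector wrt theta."""
    h = 1e-20
    th = theta.astype(complex)
    cols = []
    for j in range(theta.size):
        th[j] += 1j * h
        M0, Mw, Sigma = model.moments(th)
        cols.append(
            np.concatenate([M0.imag, Mw.imag.ravel(), Sigma.imag.ravel()]) / h
        )
        th[j] = theta[j]
    return np.column_stack(cols)


def expected_information(model: "MomentModel", theta: np.ndarray, patterns, q: int) -> np.ndarray:
    """Exact Fisher information of the packed parameters.

    For a Gaussian model the expected information in moment space is closed
    form per missingness pattern — ``kron(Sinv, X'X)`` for the mean maps and
    ``n_p/2 kron(Sinv, Sinv)`` for the covariance, with no mean-covariance
    cross terms — and maps to the packed space through the moment Jacobian.
    Used to precondition the optimizer and for expected-information SEs.
    """
    M0, Mw, Sigma = (np.real(m) for m in model.moments(theta))
    p = M0.shape[0]
    d = q + 1
    Fpi = np.zeros((p * d, p * d))
    Fcov = np.zeros((p * p, p * p))
    for pat in patterns:
        o = pat.obs
        k = o.size
        Sinv = np.linalg.inv(Sigma[np.ix_(o, o)])
        n_p = pat.Y.shape[0]
        X = np.column_stack([np.ones(n_p), pat.W])
        Sxx = X.T @ X
        idx_m = (o[:, None] * d + np.arange(d)[None, :]).ravel()
        Fpi[np.ix_(idx_m, idx_m)] += np.kron(Sinv, Sxx)
        idx_c = (o[:, None] * p + o[None, :]).ravel()
        Fcov[np.ix_(idx_c, idx_c)] += 0.5 * n_p * np.kron(Sinv, Sinv)
    J = _moment_jacobian(model, np.asarray(theta, float))
    # reorder the mean-map rows of J from [M0; Mw.ravel()] to Pi.ravel() (i, c)
    idx = np.empty(p * d, dtype=int)
    for i in range(p):
        idx[i * d] = i
        for c in range(q):
            idx[i * d + 1 + c] = p + i * q + c
    Jpi = J[idx]
    Jc = J[p + p * q :]
    return Jpi.T @ Fpi @ Jpi + Jc.T @ Fcov @ Jc


def _packed_value_and_grad(model, patterns, q, theta):
    M0, Mw, Sigma = model.moments(theta)
    out = _pattern_loglik(M0.real, Mw.real, Sigma.real, patterns, want_grad=True)
    ll = out[0]
    if not np.isfinite(ll):
        return -np.inf, np.zeros_like(theta)
    _, gM0, gMw, gS = out
    J = _moment_jacobian(model, theta)
    gm = np.concatenate([gM0, gMw.ravel(), gS.ravel()])
    return ll, J.T @ gm


# ---------------------------------------------------------------------------
# public likelihood / fitting API
# ---------------------------------------------------------------------------

def _as_matrices(cohort, spec):
    if hasattr(cohort, "to_matrices"):
        return cohort.to_matrices(spec)
    Y, W = cohort
    return np.asarray(Y, float), np.asarray(W, float)


def fiml_loglik(params: ParameterSet, cohort, spec: Optional[ModelSpec] = None) -> float:
    """Observed-data log-likelihood of ``cohort`` under ``params``.

    ``cohort`` is a CohortTable or an ``(Y, W)`` pair of value and covariate
    matrices (NaN marks missing values).  A singular restricted covariance
    returns ``-inf`` rather than raising, so optimizers can retreat.
    """
    spec = spec or default_spec()
    params.validate(spec)
    Y, W = _as_matrices(cohort, spec)
    patterns = prepare_patterns(Y, W)
    M0, Mw, Sigma = moment_maps(params, spec)
    return float(_pattern_loglik(M0, Mw, Sigma, patterns))


@dataclass
class FitOptions:
    """Optimizer and output settings.

    ``tol`` is the relative log-likelihood change declaring convergence;
    ``gtol`` the per-participant projected-gradient tolerance.  ``starts``
    jittered restarts guard against local optima (the first start is the
    supplied initial value unperturbed).
    """

    tol: float = 1e-8
    gtol: float = 1e-4
    max_iter: int = 500
    starts: int = 3
    jitter: float = 0.05
    seed: int = 0
    compute_se: bool = True
    compute_indices: bool = True
    precondition: bool = True


@dataclass
class SaturatedResult:
    Pi: np.ndarray           # (p, 1+q) regression of outcomes on [1, w]
    Sigma: np.ndarray
    loglik: float
    n_params: int
    n_iter: int
    converged: bool


@dataclass
class BaselineResult:
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n_params: int


@dataclass
class FitIndices:
    chi2: float
    df: int
    srmr: float
    cfi: float
    chi2_baseline: float
    df_baseline: int


@dataclass
class FitResult:
    """Estimates, uncertainty and fit of a FIML model fit."""

    estimates: ParameterSet
    theta: np.ndarray                      # packed estimates
    se: Optional[np.ndarray]               # SE per packed parameter, natural scale
    se_names: list
    se_natural: Optional[np.ndarray]       # natural-scale point values
    loglik: float
    n_patterns: int
    n_obs: int
    chi2: float = np.nan
    df: int = 0
    srmr: float = np.nan
    cfi: float = np.nan
    converged: bool = False
    n_iter: int = 0

    def summary(self):
        """Coefficient table (natural scale) with Wald z and p-values."""
        import pandas as pd

        se = self.se if self.se is not None else np.full(len(self.se_names), np.nan)
        est = self.se_natural
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
            pv = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"parameter": self.se_names, "estimate": est, "se": se, "z": z, "p": pv}
        )


@dataclass
class _PackedFit:
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_inf: float


def fit_moment_model(model: MomentModel, Y, W, theta0, options: Optional[FitOptions] = None,
                     preconditioner: Optional[np.ndarray] = None) -> _PackedFit:
    """Maximize the FIML likelihood of an arbitrary moment model.

    By default the search runs in coordinates whitened by the Cholesky factor
    of the Fisher information at the initial value (the packed parameters mix
    scales from mmHg variances to per-year covariate effects, which cripples
    an unpreconditioned quasi-Newton search); ``preconditioner`` accepts a
    precomputed information matrix so replicate fits can share one.

    Used both by :func:`fit` and directly with small custom moment models.
    """
    opt = options or FitOptions()
    Y = np.asarray(Y, float)
    W = np.asarray(W, float)
    patterns = prepare_patterns(Y, W)
    n = Y.shape[0]
    q = W.shape[1]
    theta0 = np.asarray(theta0, float).copy()
    k = theta0.size

    Lp = None
    if opt.precondition:
        info = preconditioner
        if info is None:
            info = expected_information(model, theta0, patterns, q)
        ridge = 1e-8 * max(1.0, np.trace(info) / k)
        for _ in range(40):
            try:
                Lp = np.linalg.cholesky(info + ridge * np.eye(k))
                break
            except np.linalg.LinAlgError:
                ridge *= 10.0

    def to_theta(phi, anchor):
        if Lp is None:
            return phi
        return anchor + np.linalg.solve(Lp.T, phi)

    rng = np.random.default_rng(opt.seed)
    best = None
    total_iter = 0
    for s in range(max(1, opt.starts)):
        anchor = theta0
        if s > 0:
            anchor = theta0 + opt.jitter * rng.standard_normal(k)

        def negf(phi, anchor=anchor):
            th = to_theta(phi, anchor)
            ll, g = _packed_value_and_grad(model, patterns, q, th)
            if not np.isfinite(ll):
                return 1e15, np.zeros_like(phi)
            if Lp is None:
                return -ll, -g
            return -ll, -np.linalg.solve(Lp, g)

        x0 = anchor.copy() if Lp is None else np.zeros(k)
        res = optimize.minimize(
            negf,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": opt.max_iter,
                "ftol": opt.tol,
                "gtol": opt.gtol * (1.0 if Lp is not None else n),
                "maxcor": 20,
            },
        )
        total_iter += res.nit
        theta_hat = to_theta(res.x, anchor)
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, theta_hat)
    ll, res, theta_hat = best
    _, g = _packed_value_and_grad(model, patterns, q, theta_hat)
    grad_inf = float(np.max(np.abs(g)))
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"FIML optimizer did not converge: {res.message}", NonConvergenceWarning
        )
    return _PackedFit(theta=theta_hat, loglik=float(ll), converged=converged,
                      n_iter=total_iter, grad_inf=grad_inf)


def fit(
    cohort,
    spec: Optional[ModelSpec] = None,
    init: Optional[ParameterSet] = None,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit the joint metabolic growth model to a cohort by FIML."""
    spec = spec or default_spec()
    opt = options or FitOptions()
    init = init or default_parameters()
    Y, W = _as_matrices(cohort, spec)
    model = JointMomentModel(spec)
    theta0 = pack_parameters(init, spec)
    pf = fit_moment_model(model, Y, W, theta0, opt)
    patterns = prepare_patterns(Y, W)

    names = _natural_names(spec)
    nat = _natural_vector_fn(spec)
    se = None
    if opt.compute_se:
        se = standard_errors(model, Y, W, pf.theta, nat_fn=nat)
    result = FitResult(
        estimates=model.unpack(pf.theta),
        theta=pf.theta,
        se=se,
        se_names=names,
        se_natural=nat(pf.theta).real,
        loglik=pf.loglik,
        n_patterns=len(patterns),
        n_obs=Y.shape[0],
        converged=pf.converged,
        n_iter=pf.n_iter,
    )
    if opt.compute_indices:
        sat = saturated_fit((Y, W))
        base = baseline_fit(Y)
        M0, Mw, Sigma = model.moments(pf.theta)
        fi = fit_indices(
            pf.loglik,
            sat,
            base,
            n_free=model.n_free,
            model_moments=(M0, Mw, Sigma),
            W=W,
        )
        result.chi2, result.df = fi.chi2, fi.df
        result.srmr, result.cfi = fi.srmr, fi.cfi
    return result


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _natural_vector_fn(spec: ModelSpec) -> Callable:
    """Map packed theta -> natural-scale parameter vector (complex-safe).

    Entries parallel the packed layout but report variances/covariances and
    residual variances on their natural scale for delta-method SEs.
    """

    def nat(theta):
        p = unpack_parameters(theta, spec)
        tril3 = [(i, j) for i in range(3) for j in range(i + 1)]
        if not spec.b2_random:
            tril3 = [(i, j) for i in range(2) for j in range(i + 1)]
        tril9 = [(i, j) for i in range(9) for j in range(i + 1)]
        parts = [
            p.alpha_b,
            p.Gamma_b.ravel(),
            np.array([p.Psi_b[i, j] for i, j in tril3]),
            p.B[_bfree()],
            p.alpha_f,
            p.Gamma_f[_gfree(spec)],
            np.array([p.Psi_zeta[i, j] for i, j in tril9]),
            np.atleast_1d(p.omega),
            p.lam[1:],
            p.nu[1:],
            p.kappa.ravel(),
            p.theta,
        ]
        return np.concatenate([np.atleast_1d(np.asarray(x)) for x in parts])

    return nat


def _bfree():
    from .model import B_FREE

    return B_FREE


def _gfree(spec):
    from .model import gamma_f_free_mask

    return gamma_f_free_mask(spec)


def _natural_names(spec: ModelSpec) -> list[str]:
    names = free_parameter_names(spec)
    out = []
    for nm in names:
        nm = nm.replace("cholPsi", "Psi").replace("log_omega", "omega")
        out.append(nm.replace("log_theta", "theta"))
    return out


def hessian_packed(model: MomentModel, Y, W, theta, step=1e-5):
    """Numerical Hessian of the log-likelihood via central differences of the
    analytic gradient."""
    patterns = prepare_patterns(np.asarray(Y, float), np.asarray(W, float))
    q = np.asarray(W).shape[1]

    def grad(th):
        return _packed_value_and_grad(model, patterns, q, th)[1]

    k = theta.size
    H = np.zeros((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        e = np.zeros(k)
        e[j] = h
        H[:, j] = (grad(theta + e) - grad(theta - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def standard_errors(model, Y, W, theta, nat_fn=None, step=1e-5, method="expected"):
    """Delta-method natural-scale SEs from the inverse information matrix.

    ``method="expected"`` (default) uses the exact Fisher information, which
    is positive definite whenever the model is locally identified and cheap
    to evaluate; ``method="observed"`` inverts the numerical Hessian of the
    log-likelihood (central differences of the analytic gradient).  A
    non-positive-definite information matrix yields NaN for the affected
    parameters, with a warning, rather than an exception.
    """
    if method == "expected":
        patterns = prepare_patterns(np.asarray(Y, float), np.asarray(W, float))
        info = expected_information(model, theta, patterns, np.asarray(W).shape[1])
    elif method == "observed":
        info = -hessian_packed(model, Y, W, theta, step=step)
    else:
        raise ValueError(f"unknown SE method {method!r}")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    if np.any(np.diag(cov) <= 0):
        warnings.warn(
            "observed information is not positive definite; SEs undefined for "
            "some parameters", NonConvergenceWarning,
        )
    if nat_fn is None:
        var = np.diag(cov)
        return np.sqrt(np.where(var > 0, var, np.nan))
    # complex-step Jacobian of the natural parameter map
    h = 1e-20
    th = theta.astype(complex)
    Jn = np.empty((nat_fn(theta).size, theta.size))
    for j in range(theta.size):
        th[j] += 1j * h
        Jn[:, j] = nat_fn(th).imag / h
        th[j] = theta[j]
    var = np.einsum("ij,jk,ik->i", Jn, cov, Jn)
    return np.sqrt(np.where(var > 0, var, np.nan))


# ---------------------------------------------------------------------------
# saturated and baseline reference models
# ---------------------------------------------------------------------------

def saturated_fit(cohort, spec: Optional[ModelSpec] = None, use_covariates: bool = True,
                  tol: float = 1e-9, max_iter: int = 5000) -> SaturatedResult:
    """Unrestricted means-and-covariance model by FIML, via EM.

    With covariates, the unrestricted model is the multivariate regression of
    the outcome vector on ``[1, w]`` with unstructured residual covariance —
    the frame in which the structured model is nested.  The EM M-step is
    closed form, so each iteration is exact; with complete data the first
    iteration already returns the ML (divisor n) moments.
    """
    Y, W = _as_matrices(cohort, spec or default_spec())
    Y = np.asarray(Y, float)
    W = np.asarray(W, float)
    n, p = Y.shape
    X = np.column_stack([np.ones(n), W]) if use_covariates else np.ones((n, 1))
    d = X.shape[1]
    mask = np.isnan(Y)
    if np.any(mask.all(axis=1)):
        raise ValueError("every participant must have at least one observed value")

    # initialize from mean-imputed OLS
    Yf = Y.copy()
    col_mean = np.nanmean(Y, axis=0)
    Yf[mask] = np.take(col_mean, np.where(mask)[1])
    Sxx = X.T @ X
    Pi = np.linalg.solve(Sxx, X.T @ Yf).T
    Resid = Yf - X @ Pi.T
    Sigma = Resid.T @ Resid / n + 1e-6 * np.eye(p)

    keys, inverse = np.unique(mask, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inverse == g) for g in range(keys.shape[0])]

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Syx = np.zeros((p, d))
        Syy = np.zeros((p, p))
        ll = 0.0
        for g, rows in enumerate(groups):
            o = np.flatnonzero(~keys[g])
            m = np.flatnonzero(keys[g])
            Xg = X[rows]
            Yo = Y[np.ix_(rows, o)]
            So = Sigma[np.ix_(o, o)]
            c, low = _cho_factor(So)
            Ro = Yo - Xg @ Pi[o].T
            Si_Ro = _cho_solve((c, low), Ro.T).T
            k = o.size
            ll += -0.5 * (
                len(rows) * (k * _LOG2PI + 2.0 * np.log(np.diag(c)).sum())
                + float(np.sum(Ro * Si_Ro))
            )
            Yhat = np.empty((len(rows), p))
            Yhat[:, o] = Yo
            if m.size:
                A = _cho_solve((c, low), Sigma[np.ix_(o, m)]).T   # (m, o) @ So^-1
                Yhat[:, m] = Xg @ Pi[m].T + Ro @ A.T
                Cmm = Sigma[np.ix_(m, m)] - A @ Sigma[np.ix_(o, m)]
                Syy[np.ix_(m, m)] += len(rows) * Cmm
            Syx += Yhat.T @ Xg
            Syy += Yhat.T @ Yhat
        Pi = np.linalg.solve(Sxx, Syx.T).T
        Sigma = (Syy - Pi @ Syx.T) / n
        Sigma = 0.5 * (Sigma + Sigma.T)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    # final observed-data loglik at the last parameter update
    patterns = prepare_patterns(Y, X[:, 1:] if d > 1 else np.zeros((n, 0)))
    M0 = Pi[:, 0]
    Mw = Pi[:, 1:] if d > 1 else np.zeros((p, 0))
    ll_final = _pattern_loglik(M0, Mw, Sigma, patterns)
    n_params = p * d + p * (p + 1) // 2
    return SaturatedResult(Pi=Pi, Sigma=Sigma, loglik=float(ll_final),
                           n_params=n_params, n_iter=it, converged=converged)


def baseline_fit(Y) -> BaselineResult:
    """Independence model: free means and variances, zero covariances.

    With a diagonal covariance and no cross-variable structure the FIML
    likelihood factorizes per variable, so the ML solution is each variable's
    observed-value mean and (divisor n) variance in closed form.
    """
    Y = np.asarray(Y, float)
    p = Y.shape[1]
    means = np.nanmean(Y, axis=0)
    variances = np.nanvar(Y, axis=0)
    ll = 0.0
    for j in range(p):
        y = Y[~np.isnan(Y[:, j]), j]
        if y.size == 0:
            raise ValueError(f"variable {j} has no observed values")
        ll += -0.5 * np.sum(_LOG2PI + np.log(variances[j]) + (y - means[j]) ** 2 / variances[j])
    return BaselineResult(means=means, variances=variances, loglik=float(ll),
                          n_params=2 * p)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def srmr_from_moments(model_moments, saturated: SaturatedResult, W) -> float:
    """Standardized root mean square residual, including mean residuals.

    Residuals contrast the unrestricted estimates with the model-implied
    moments: covariance residuals are standardized by the unrestricted SDs,
    mean residuals (evaluated at the average covariate profile) likewise, and
    variance residuals by the unrestricted variances.  The RMS runs over the
    unique elements (p means + p(p+1)/2 (co)variances).
    """
    M0, Mw, Sigma_m = model_moments
    W = np.asarray(W, float)
    p = M0.shape[0]
    wbar = W.mean(axis=0) if W.size else np.zeros(0)
    d = saturated.Pi.shape[1]
    m_sat = saturated.Pi[:, 0] + (saturated.Pi[:, 1:] @ wbar[: d - 1] if d > 1 else 0.0)
    m_mod = M0 + (Mw @ wbar if W.size and Mw.shape[1] else 0.0)
    S = saturated.Sigma
    sd = np.sqrt(np.diag(S))
    total = 0.0
    count = 0
    for i in range(p):
        total += ((m_sat[i] - m_mod[i]) / sd[i]) ** 2
        count += 1
        for j in range(i + 1):
            total += ((S[i, j] - Sigma_m[i, j]) / (sd[i] * sd[j])) ** 2
            count += 1
    return float(np.sqrt(total / count))


def fit_indices(model_loglik: float, saturated: SaturatedResult,
                baseline: BaselineResult, n_free: int,
                model_moments=None, W=None) -> FitIndices:
    """Likelihood-ratio chi-square, SRMR and CFI.

    ``chi2 = 2 (logL_sat − logL_model)``;
    ``CFI = 1 − max(chi2_M − df_M, 0) / max(chi2_B − df_B, chi2_M − df_M, 0)``.
    """
    df_m = saturated.n_params - n_free
    df_b = saturated.n_params - baseline.n_params
    if df_m <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    chi2_m = 2.0 * (saturated.loglik - model_loglik)
    chi2_b = 2.0 * (saturated.loglik - baseline.loglik)
    if chi2_m < 0:
        if chi2_m < -1e-6 * max(1.0, abs(saturated.loglik)):
            warnings.warn("model log-likelihood exceeds the saturated log-likelihood",
                          NonConvergenceWarning)
        chi2_m = 0.0
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - max(chi2_m - df_m, 0.0) / denom
    cfi = float(min(max(cfi, 0.0), 1.0))
    srmr = np.nan
    if model_moments is not None:
        srmr = srmr_from_moments(model_moments, saturated, W if W is not None else np.zeros((1, 0)))
    return FitIndices(chi2=float(chi2_m), df=int(df_m), srmr=srmr, cfi=cfi,
                      chi2_baseline=float(chi2_b), df_baseline=int(df_b))


def classify_srmr(srmr: float, cutoff: float = 0.08) -> str:
    """'acceptable' if at or under the conventional 0.08 cut-off."""
    return "acceptable" if srmr <= cutoff else "above"


def classify_cfi(cfi: float, cutoff: float = 0.95) -> str:
    """'acceptable' if at or above the conventional 0.95 cut-off."""
    return "acceptable" if cfi >= cutoff else "below"
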