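"""Maximum-likelihood logistic regression with Gaussian random intercepts.

The marginal likelihood is approximated by a Laplace expansion around the
conditional mode of the random effects (the standard approximate-likelihood
method for binary mixed models):

    l(beta, sigma) = log p(y | beta, u_hat) - u_hat' D^-1 u_hat / 2
                     - (log det D + log det(Z' W Z + D^-1)) / 2

with D = blockdiag(sigma_l^2 I). Estimation runs in two stages: a fast
penalised-likelihood stage jointly maximising over (beta, u) to obtain
starting values, then a quasi-Newton maximisation of the Laplace objective
over (beta, log sigma) with the random effects profiled by inner Newton
iterations — the same scheme as the widely used Laplace (nAGQ=1) fitters, so
estimates are comparable to them to high accuracy. One or more
random-intercept levels are supported; nested levels (patients within
practices) are passed as separate grouping factors, which is equivalent for
nested labels.

Fixed-effect covariances come from the fixed-effects block of the inverse
joint observed information at the optimum (conditional on the estimated
variances), matching common mixed-model practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize, minimize_scalar
from scipy.sparse.linalg import splu
from scipy.special import expit

from .errors import EstimationError

_SIGMA_LO, _SIGMA_HI = 1e-4, 8.0


@dataclass
class MixedLogitFit:
    """Result of one Laplace fit."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    names: list
    sigmas: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    group_counts: tuple
    u: np.ndarray = field(repr=False, default=None)
    message: str = ""


def _loglik(y, eta):
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _newton(A, y, pen, v0, max_iter=200, tol=1e-12, diag_hessian=None):
    """Maximise the penalised log-likelihood over v by damped Newton steps.

    ``diag_hessian(w)`` may supply the diagonal of A' W A + diag(pen) when the
    Hessian is known diagonal (single random-intercept level), avoiding the
    sparse factorisation."""
    v = v0.copy()
    eta = A @ v

    def objective(v, eta):
        return _loglik(y, eta) - 0.5 * float(pen @ (v * v))

    f = objective(v, eta)
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = A.T @ (y - mu) - pen * v
        if np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
        if diag_hessian is not None:
            delta = grad / diag_hessian(w)
        else:
            H = (A.T.multiply(w) @ A) + sp.diags(pen)
            try:
                delta = splu(H.tocsc()).solve(grad)
            except RuntimeError as exc:  # singular system
                return v, eta, f, False, f"newton solve failed: {exc}"
        step = 1.0
        while step > 1e-12:
            v_new = v + step * delta
            eta_new = A @ v_new
            f_new = objective(v_new, eta_new)
            if f_new >= f - 1e-14:
                break
            step /= 2.0
        improved = f_new - f
        v, eta, f = v_new, eta_new, f_new
        if abs(improved) < tol * (1.0 + abs(f)):
            converged = True
            break
    return v, eta, f, converged, ""


def fit_logistic_mixed(
    y,
    X,
    groups,
    names=None,
    start_sigma=0.5,
) -> MixedLogitFit:
    """Fit logit(P(y=1)) = X beta + sum_l u_l[groups_l] with u_l ~ N(0, s_l^2).

    ``groups`` is a list of integer-coded arrays (one per random-intercept
    level). Raises EstimationError for single-class outcomes; non-convergence
    or separation is flagged on the result, never silently replaced.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n == 0:
        raise EstimationError("no observations")
    if y.min() == y.max():
        raise EstimationError("outcome has a single class; model not estimable")
    if not np.isfinite(X).all():
        raise EstimationError("non-finite values in the design matrix")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if not groups:
        raise EstimationError("at least one random-intercept level is required")

    qs, zblocks, codes_list = [], [], []
    for codes in groups:
        codes = np.asarray(codes)
        if codes.min() < 0:
            raise EstimationError("negative group codes")
        q = int(codes.max()) + 1
        qs.append(q)
        codes_list.append(codes)
        zblocks.append(sp.csc_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q)))
    Z = sp.hstack(zblocks, format="csc")
    A = sp.hstack([sp.csc_matrix(X)] + zblocks, format="csc")
    n_levels = len(qs)
    q_total = int(sum(qs))
    single_level = n_levels == 1

    def pen_u_vector(sigmas):
        return np.concatenate([
            np.full(q, 1.0 / (s * s)) for q, s in zip(qs, sigmas)
        ])

    # ---------------- stage 1: joint penalised fit for starting values
    joint_state = {"v": np.zeros(p + q_total)}

    def stage1_neg(log_sigma):
        sigmas = np.clip(np.exp(np.atleast_1d(log_sigma)), _SIGMA_LO, _SIGMA_HI)
        pen = np.concatenate([np.zeros(p), pen_u_vector(sigmas)])
        v, eta, _, ok, _ = _newton(A, y, pen, joint_state["v"])
        if ok:
            joint_state["v"] = v
        return -_laplace_from_mode(y, eta, v, pen, Z, p, qs, sigmas, single_level,
                                   codes_list)

    if single_level:
        res1 = minimize_scalar(stage1_neg, bounds=(np.log(1e-3), np.log(_SIGMA_HI)),
                               method="bounded", options={"xatol": 1e-4})
        sig0 = np.array([np.exp(res1.x)])
    else:
        res1 = minimize(stage1_neg, x0=np.full(n_levels, np.log(start_sigma)),
                        method="Nelder-Mead",
                        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
        sig0 = np.exp(res1.x)
    beta0 = joint_state["v"][:p]

    # ---------------- stage 2: Laplace objective over (beta, log sigma)
    u_state = {"u": joint_state["v"][p:].copy()}

    def u_diag_factory(pen_u, codes):
        def diag(w):
            return np.bincount(codes, weights=w, minlength=qs[0]) + pen_u
        return diag

    def neg_laplace(params):
        beta = params[:p]
        sigmas = np.clip(np.exp(params[p:]), _SIGMA_LO, _SIGMA_HI)
        pen_u = pen_u_vector(sigmas)
        offset = X @ beta
        # profile u at fixed beta: Newton on the offset model
        u, eta_u, _, ok, _ = _newton_offset(Z, y, offset, pen_u, u_state["u"],
                                            u_diag_factory(pen_u, codes_list[0])
                                            if single_level else None)
        if ok:
            u_state["u"] = u
        v = np.concatenate([beta, u])
        pen_full = np.concatenate([np.zeros(p), pen_u])
        return -_laplace_from_mode(y, eta_u, v, pen_full, Z, p, qs, sigmas,
                                   single_level, codes_list)

    x0 = np.concatenate([beta0, np.log(np.clip(sig0, _SIGMA_LO, _SIGMA_HI))])
    bounds = [(None, None)] * p + [(np.log(_SIGMA_LO), np.log(_SIGMA_HI))] * n_levels
    res2 = minimize(neg_laplace, x0=x0, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})

    beta = res2.x[:p]
    sigmas = np.clip(np.exp(res2.x[p:]), _SIGMA_LO, _SIGMA_HI)
    loglik = -float(res2.fun)

    # final conditional mode and joint information for the covariance
    pen_u = pen_u_vector(sigmas)
    offset = X @ beta
    u, eta, _, inner_ok, msg = _newton_offset(
        Z, y, offset, pen_u, u_state["u"],
        u_diag_factory(pen_u, codes_list[0]) if single_level else None,
    )
    mu = expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    pen_full = np.concatenate([np.zeros(p), pen_u])
    H = (A.T.multiply(w) @ A) + sp.diags(pen_full)
    lu = splu(H.tocsc())
    cols = np.column_stack([
        lu.solve(np.eye(p + q_total, 1, -j).ravel()) for j in range(p)
    ])
    vcov = cols[:p, :]
    vcov = 0.5 * (vcov + vcov.T)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    separated = bool(np.max(np.abs(beta)) > 15.0)
    return MixedLogitFit(
        beta=beta,
        se=se,
        vcov=vcov,
        names=names,
        sigmas=sigmas,
        loglik=loglik,
        converged=bool(res2.success) and inner_ok and not separated,
        n_obs=n,
        group_counts=tuple(qs),
        u=u,
        message=msg or ("possible separation" if separated else ""),
    )


def _newton_offset(Z, y, offset, pen_u, u0, diag_fn):
    """Newton over the random effects only, with X beta held as an offset."""
    u = u0.copy()
    eta = offset + Z @ u

    def objective(u, eta):
        return _loglik(y, eta) - 0.5 * float(pen_u @ (u * u))

    f = objective(u, eta)
    converged = False
    for _ in range(200):
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = Z.T @ (y - mu) - pen_u * u
        if np.max(np.abs(grad)) < 1e-10:
            converged = True
            break
        if diag_fn is not None:
            delta = grad / diag_fn(w)
        else:
            H = (Z.T.multiply(w) @ Z) + sp.diags(pen_u)
            try:
                delta = splu(H.tocsc()).solve(grad)
            except RuntimeError as exc:
                return u, eta, f, False, f"newton solve failed: {exc}"
        step = 1.0
        while step > 1e-12:
            u_new = u + step * delta
            eta_new = offset + Z @ u_new
            f_new = objective(u_new, eta_new)
            if f_new >= f - 1e-14:
                break
            step /= 2.0
        improved = f_new - f
        u, eta, f = u_new, eta_new, f_new
        if abs(improved) < 1e-13 * (1.0 + abs(f)):
            converged = True
            break
    return u, eta, f, converged, ""


def _laplace_from_mode(y, eta, v, pen_full, Z, p, qs, sigmas, single_level,
                       codes_list):
    """Laplace log-likelihood given the conditional mode."""
    mu = expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    if single_level:
        wsum = np.bincount(codes_list[0], weights=w, minlength=qs[0])
        logdet_huu = float(np.sum(np.log(wsum + pen_full[p:])))
    else:
        huu = (Z.T.multiply(w) @ Z) + sp.diags(pen_full[p:])
        lu = splu(huu.tocsc())
        logdet_huu = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    logdet_d = float(sum(q * 2.0 * np.log(s) for q, s in zip(qs, sigmas)))
    return (
        _loglik(y, eta)
        - 0.5 * float(pen_full @ (v * v))
        - 0.5 * (logdet_d + logdet_huu)
    )
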