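"""Profiled REML for linear models with crossed random intercepts.

Model: y = X beta + sum_k Z_k u_k + e, with u_k ~ N(0, sigma_k^2 I) for each
crossed grouping factor k (e.g. origin airport, destination airport,
degree-link-type group) and e ~ N(0, sigma^2 I).

The restricted likelihood is profiled over beta and sigma^2 and minimised in
the variance ratios lambda_k = sigma_k^2 / sigma^2 (on a log scale).  All
linear algebra goes through the mixed-model (Henderson) equations, so each
evaluation costs one Cholesky of the q x q matrix Z'Z + diag(1/lambda) with
q the total number of random-effect levels — cheap even for thousands of
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp

_LOG_LAMBDA_MIN = -16.0
_LOG_LAMBDA_MAX = 10.0


@dataclass
class RemlResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    varcomps: dict           # term -> sigma_k^2
    blups: dict              # term -> (levels array, u array, conditional var array)
    converged: bool
    reml_criterion: float
    n_iter: int


def _encode_groups(groups: dict[str, np.ndarray]):
    """One-hot encode each grouping factor; returns (Z sparse, slices, levels)."""
    blocks, slices, levels = [], {}, {}
    start = 0
    for name, codes in groups.items():
        codes = np.asarray(codes)
        lv, idx = np.unique(codes, return_inverse=True)
        n, q = codes.size, lv.size
        z = sp.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, q))
        blocks.append(z)
        slices[name] = slice(start, start + q)
        levels[name] = lv
        start += q
    return sp.hstack(blocks, format="csr"), slices, levels


def _ols_result(X, y) -> RemlResult:
    n, p = X.shape
    XtX = X.T @ X
    beta = sla.solve(XtX, X.T @ y, assume_a="pos")
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid), 1e-300) / (n - p)
    return RemlResult(beta=beta, cov_beta=sigma2 * np.linalg.inv(XtX),
                      sigma2=float(sigma2), varcomps={}, blups={},
                      converged=True, reml_criterion=float((n - p) * np.log(sigma2)),
                      n_iter=1)


def fit_crossed_reml(X: np.ndarray, y: np.ndarray,
                     groups: dict[str, np.ndarray],
                     maxiter: int = 500,
                     fixed_log_lambda: dict[str, float] | None = None) -> RemlResult:
    """Fit by REML; ``groups`` maps term name -> per-row group codes.

    ``fixed_log_lambda`` pins log(sigma_k^2 / sigma^2) per term instead of
    optimising (used to force variance components to given values; an empty
    ``groups`` dict degenerates to OLS).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    if not groups:
        return _ols_result(X, y)
    Z, slices, levels = _encode_groups(groups)
    q = Z.shape[1]
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    terms = list(groups)
    qk = np.array([slices[t].stop - slices[t].start for t in terms])

    def pieces(log_lam):
        lam = np.exp(np.clip(log_lam, _LOG_LAMBDA_MIN, _LOG_LAMBDA_MAX))
        dinv = np.concatenate([np.full(nk, 1.0 / lk) for nk, lk in zip(qk, lam)])
        A = ZtZ + np.diag(dinv)
        cF = sla.cho_factor(A, lower=True, check_finite=False)
        AiZtX = sla.cho_solve(cF, ZtX, check_finite=False)
        AiZty = sla.cho_solve(cF, Zty, check_finite=False)
        XtVX = XtX - ZtX.T @ AiZtX
        XtVy = Xty - ZtX.T @ AiZty
        yVy = yty - float(Zty @ AiZty)
        beta = sla.solve(XtVX, XtVy, assume_a="pos")
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        sigma2 = rss / (n - p)
        logdetA = 2.0 * np.sum(np.log(np.diag(cF[0])))
        logdetV = logdetA + float(np.sum(qk * np.log(lam)))
        sgn, logdetXtVX = np.linalg.slogdet(XtVX)
        crit = (n - p) * np.log(sigma2) + logdetV + logdetXtVX
        return crit, lam, beta, sigma2, XtVX, cF

    nev = 0

    def objective(log_lam):
        nonlocal nev
        nev += 1
        return pieces(log_lam)[0]

    if fixed_log_lambda is not None:
        xhat = np.array([fixed_log_lambda[t] for t in terms])
        crit, lam, beta, sigma2, XtVX, cF = pieces(xhat)
        converged, n_eval = True, 1
    else:
        x0 = np.zeros(len(terms))
        res = sopt.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8})
        crit, lam, beta, sigma2, XtVX, cF = pieces(res.x)
        converged, n_eval = bool(res.success or res.status == 1), nev
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    # BLUPs and their conditional variances
    resid = Zty - ZtX @ beta
    u = sla.cho_solve(cF, resid, check_finite=False)
    Ainv_diag = np.diag(sla.cho_solve(cF, np.eye(len(resid)), check_finite=False))
    blups = {}
    varcomps = {}
    for t in terms:
        s = slices[t]
        varcomps[t] = float(lam[terms.index(t)] * sigma2)
        blups[t] = (levels[t], u[s].copy(), sigma2 * Ainv_diag[s].copy())
    return RemlResult(beta=beta, cov_beta=cov_beta, sigma2=float(sigma2),
                      varcomps=varcomps, blups=blups, converged=converged,
                      reml_criterion=float(crit), n_iter=n_eval)
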