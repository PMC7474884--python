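"""Vectorised logistic regression across many species.

All species share the design matrix. Two safeguards keep fits finite and
comparable in the presence of complete or quasi-complete separation
(common with rare species): linear predictors are capped at |eta| <=
ETA_CAP, with the IRLS working weights floored so the working response
stays on the capped scale, and any step that would increase a species'
deviance is halved (up to 10 times). Fits start from the intercept-only
solution, so the final deviance never exceeds the null deviance.

Two equivalent engines are provided: a numba-compiled per-species loop
(default when numba is importable) and a pure-numpy batched fallback; both
implement the same iteration and stopping rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["BatchGlmFit", "fit_logistic_batch", "bernoulli_loglik"]

ETA_CAP = 30.0
MAX_ITER = 100
DEV_TOL = 1e-8
_W_FLOOR = 1e-4
_MAX_HALVINGS = 10
_RIDGE = 1e-10


@dataclass(frozen=True)
class BatchGlmFit:
    """Per-species logistic fits on a shared design.

    coef: (k, p) coefficients; loglik/deviance: per-species; separation
    marks species whose linear predictor hit the cap at convergence.
    """

    coef: np.ndarray
    loglik: np.ndarray
    deviance: np.ndarray
    separation: np.ndarray
    converged: np.ndarray
    n_iter: int

    @property
    def n_params(self) -> int:
        return self.coef.shape[0]

    def aic(self) -> np.ndarray:
        """Per-species AIC = 2k - 2 loglik."""
        return 2.0 * self.n_params - 2.0 * self.loglik


def bernoulli_loglik(Y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-species Bernoulli log-likelihood at linear predictor eta.

    Uses the numerically stable form  y*eta - log(1 + exp(eta)).
    """
    return (Y * eta - np.logaddexp(0.0, eta)).sum(axis=0)


def _null_start(Y: np.ndarray, k: int, eta_cap: float) -> np.ndarray:
    """Intercept-only starting values (capped logit of prevalence)."""
    prev = Y.mean(axis=0)
    with np.errstate(divide="ignore"):
        logit = np.log(prev) - np.log1p(-prev)
    beta = np.zeros((k, Y.shape[1]))
    beta[0] = np.clip(logit, -eta_cap, eta_cap)
    return beta


def _check_inputs(X, Y, beta0, eta_cap):
    X = np.ascontiguousarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = np.ascontiguousarray(Y)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y must be binary (0/1)")
    if beta0 is None:
        beta = _null_start(Y, X.shape[1], eta_cap)
    else:
        beta = np.array(beta0, dtype=float)
        if beta.shape != (X.shape[1], Y.shape[1]):
            raise ValueError("beta0 has wrong shape")
    return X, Y, np.ascontiguousarray(beta)


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _irls_species(X, y, b, eta_cap, max_iter, tol, w_floor, ridge):
        n, k = X.shape
        eta = np.empty(n)
        for i in range(n):
            v = 0.0
            for a in range(k):
                v += X[i, a] * b[a]
            eta[i] = min(max(v, -eta_cap), eta_cap)
        dev = 0.0
        for i in range(n):
            dev += -2.0 * (y[i] * eta[i] - (max(eta[i], 0.0) + np.log1p(np.exp(-abs(eta[i])))))
        converged = False
        it = 0
        A = np.empty((k, k))
        L = np.empty((k, k))
        rhs = np.empty(k)
        nb = np.empty(k)
        neta = np.empty(n)
        for it in range(1, max_iter + 1):
            for a in range(k):
                rhs[a] = 0.0
                for c in range(k):
                    A[a, c] = 0.0
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                w = max(mu * (1.0 - mu), w_floor)
                z = eta[i] + (y[i] - mu) / w
                z = min(max(z, -2.0 * eta_cap), 2.0 * eta_cap)
                for a in range(k):
                    wxa = w * X[i, a]
                    rhs[a] += wxa * z
                    for c in range(a, k):
                        A[a, c] += wxa * X[i, c]
            for a in range(k):
                A[a, a] += ridge
                for c in range(a + 1, k):
                    A[c, a] = A[a, c]
            # Cholesky solve (A is symmetric positive definite)
            for c in range(k):
                s = A[c, c]
                for t in range(c):
                    s -= L[c, t] * L[c, t]
                L[c, c] = np.sqrt(max(s, 1e-300))
                for r2 in range(c + 1, k):
                    s2 = A[r2, c]
                    for t in range(c):
                        s2 -= L[r2, t] * L[c, t]
                    L[r2, c] = s2 / L[c, c]
            for a in range(k):  # forward substitution L y = rhs
                s = rhs[a]
                for t in range(a):
                    s -= L[a, t] * nb[t]
                nb[a] = s / L[a, a]
            for a in range(k - 1, -1, -1):  # back substitution L' x = y
                s = nb[a]
                for t in range(a + 1, k):
                    s -= L[t, a] * nb[t]
                nb[a] = s / L[a, a]
            # candidate deviance with step halving
            ndev = 0.0
            for h in range(11):  # initial step + up to 10 halvings
                if h > 0:
                    for a in range(k):
                        nb[a] = 0.5 * (nb[a] + b[a])
                ndev = 0.0
                for i in range(n):
                    v = 0.0
                    for a in range(k):
                        v += X[i, a] * nb[a]
                    neta[i] = min(max(v, -eta_cap), eta_cap)
                    ndev += -2.0 * (
                        y[i] * neta[i]
                        - (max(neta[i], 0.0) + np.log1p(np.exp(-abs(neta[i]))))
                    )
                if ndev <= dev + 1e-12:
                    break
            if ndev > dev + 1e-12:
                ndev = dev  # keep previous iterate
            else:
                for a in range(k):
                    b[a] = nb[a]
                for i in range(n):
                    eta[i] = neta[i]
            delta = abs(ndev - dev)
            dev = ndev
            if delta < tol:
                converged = True
                break
        sep = False
        for i in range(n):
            if abs(eta[i]) >= eta_cap - 1e-4:
                sep = True
                break
        return dev, converged, sep, it

    @numba.njit(cache=True, parallel=False)
    def _irls_all(X, Y, beta, eta_cap, max_iter, tol, w_floor, ridge):
        p = Y.shape[1]
        dev = np.empty(p)
        conv = np.zeros(p, numba.boolean)
        sep = np.zeros(p, numba.boolean)
        worst = 0
        for j in range(p):
            d, c, s, it = _irls_species(
                X, Y[:, j], beta[:, j], eta_cap, max_iter, tol, w_floor, ridge
            )
            dev[j] = d
            conv[j] = c
            sep[j] = s
            if it > worst:
                worst = it
        return dev, conv, sep, worst


def _fit_numba(X, Y, beta, eta_cap, max_iter, tol) -> BatchGlmFit:
    beta = np.asfortranarray(beta)
    dev, conv, sep, worst = _irls_all(
        X, np.asfortranarray(Y), beta, eta_cap, max_iter, tol, _W_FLOOR, _RIDGE
    )
    return BatchGlmFit(
        coef=np.ascontiguousarray(beta),
        loglik=-dev / 2.0,
        deviance=dev,
        separation=sep,
        converged=conv,
        n_iter=int(worst),
    )


def _fit_numpy(X, Y, beta, eta_cap, max_iter, tol) -> BatchGlmFit:
    n, k = X.shape
    p = Y.shape[1]
    eye = _RIDGE * np.eye(k)
    XX = X[:, :, None] * X[:, None, :]  # (n, k, k), shared across species
    eta = np.clip(X @ beta, -eta_cap, eta_cap)
    dev = -2.0 * bernoulli_loglik(Y, eta)
    done = np.zeros(p, dtype=bool)
    active = np.arange(p)
    it = 0
    for it in range(1, max_iter + 1):
        Ya, ea, ba, da = Y[:, active], eta[:, active], beta[:, active], dev[active]
        mu = 1.0 / (1.0 + np.exp(-ea))
        w = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        z = np.clip(ea + (Ya - mu) / w, -2.0 * eta_cap, 2.0 * eta_cap)
        xtwx = np.tensordot(w.T, XX, axes=(1, 0)) + eye
        xtwz = (w * z).T @ X
        nb = np.linalg.solve(xtwx, xtwz[..., None])[..., 0].T
        ne = np.clip(X @ nb, -eta_cap, eta_cap)
        nd = -2.0 * bernoulli_loglik(Ya, ne)
        for _ in range(_MAX_HALVINGS):
            worse = np.flatnonzero(nd > da + 1e-12)
            if not worse.size:
                break
            nb[:, worse] = (nb[:, worse] + ba[:, worse]) / 2.0
            ne[:, worse] = np.clip(X @ nb[:, worse], -eta_cap, eta_cap)
            nd[worse] = -2.0 * bernoulli_loglik(Ya[:, worse], ne[:, worse])
        worse = np.flatnonzero(nd > da + 1e-12)
        if worse.size:  # keep the previous iterate for those species
            nb[:, worse], ne[:, worse], nd[worse] = (
                ba[:, worse], ea[:, worse], da[worse],
            )
        settled = np.abs(nd - da) < tol
        beta[:, active], eta[:, active], dev[active] = nb, ne, nd
        done[active[settled]] = True
        active = active[~settled]
        if not active.size:
            break
    return BatchGlmFit(
        coef=beta,
        loglik=-dev / 2.0,
        deviance=dev,
        separation=(np.abs(eta) >= eta_cap - 1e-4).any(axis=0),
        converged=done,
        n_iter=it,
    )


def fit_logistic_batch(
    X: np.ndarray,
    Y: np.ndarray,
    beta0: np.ndarray | None = None,
    eta_cap: float = ETA_CAP,
    max_iter: int = MAX_ITER,
    tol: float = DEV_TOL,
    engine: str | None = None,
) -> BatchGlmFit:
    """Fit independent logistic regressions of every column of Y on X.

    Parameters
    ----------
    X : (n, k) design matrix (shared across species); column 0 is assumed
        to be the intercept when no warm start is given.
    Y : (n, p) binary responses, one column per species.
    beta0 : optional (k, p) warm start.
    engine : "numba", "numpy" or None (auto).

    IRLS stops for a species when its deviance changes by less than
    ``tol``, or after ``max_iter`` iterations.
    """
    X, Y, beta = _check_inputs(X, Y, beta0, eta_cap)
    if engine is None:
        engine = "numba" if _HAVE_NUMBA else "numpy"
    if engine == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is not importable")
    fit = _fit_numba if engine == "numba" else _fit_numpy
    return fit(X, Y, beta, eta_cap, max_iter, tol)
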