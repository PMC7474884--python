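"""Transformation-based RDA with forward selection (double stopping rule).

Binary community data are Ochiai-transformed (each site row divided by the
square root of its species count, the presence/absence analogue of the
Hellinger transformation), then regressed on spatial eigenvectors by
redundancy analysis: multivariate least squares on column-centred data,
summarised by the joint R^2 = SS(fitted)/SS(total), Ezekiel's adjusted R^2
and a pseudo-F. Significance is assessed by permutation: the global test
permutes whole rows of the response; the sequential (partial) tests permute
residuals of the reduced model containing the already-selected variables.

Forward selection follows the double stopping criterion: selection only
starts if the global test (all variables) is significant at alpha; at each
step the candidate giving the largest adjusted R^2 is tested, and selection
stops when that candidate is non-significant or when adding it would push
the adjusted R^2 above that of the global model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "ochiai_transform",
    "rda_stats",
    "permutation_pvalue",
    "forward_select_rda",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for forward selection: alpha and permutation count."""

    alpha: float = 0.05
    nperm: int = 999

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.nperm < 99:
            raise ValueError("need at least 99 permutations")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a variable-selection run (RDA/FW or GLM/AIC).

    ``selected`` holds 1-based predictor indices in acceptance order.
    ``steps`` is one record per examined step (accepted or stopping);
    ``coef_det`` is the coefficient of determination of the final model —
    adjusted R^2 for RDA, D-value for GLMs.
    """

    method: str
    selected: tuple[int, ...]
    steps: list[dict] = field(default_factory=list, compare=False)
    stop_reason: str = ""
    coef_det: float = float("nan")
    global_adj_r2: float = float("nan")
    global_p: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def ochiai_transform(Y: np.ndarray) -> np.ndarray:
    """Divide each site row by the square root of its species count.

    Non-empty rows end up with unit Euclidean norm (the Ochiai / binary
    Hellinger transformation). Empty sites are kept as all-zero rows and
    logged, not dropped.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("community matrix must be binary (0/1)")
    richness = Y.sum(axis=1)
    empty = richness == 0
    if empty.any():
        logger.warning(
            "ochiai_transform: %d empty site row(s) kept as zeros", int(empty.sum())
        )
    scale = np.where(empty, 1.0, np.sqrt(np.where(empty, 1.0, richness)))
    return Y / scale[:, None]


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def _orthonormal_columns(Xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space; errors if rank-deficient."""
    if Xc.shape[1] == 0:
        return Xc
    q, r = np.linalg.qr(Xc)
    diag = np.abs(np.diag(r))
    if diag.min() <= _RANK_TOL * max(diag.max(), 1.0):
        raise ValueError("rank-deficient predictor subset")
    return q


def reduce_response(Ytc: np.ndarray) -> np.ndarray:
    """Replace a wide centred response by its principal-coordinate scores.

    Every RDA statistic here depends on the response only through the
    site-by-site cross-product Ytc Ytc'; the scores U S from the SVD
    Ytc = U S V' have the same cross-product with at most n columns, which
    keeps permutation loops cheap for species-rich data. Exact, not an
    approximation.
    """
    n, p = Ytc.shape
    if p <= n:
        return Ytc
    U, s, _ = np.linalg.svd(Ytc, full_matrices=False)
    return U * s


def rda_stats(Yt: np.ndarray, Xsub: np.ndarray) -> tuple[float, float, float]:
    """(R^2, adjusted R^2, pseudo-F) of the RDA of Yt on Xsub.

    Both matrices are column-centred internally; R^2 is the fraction of the
    total sum of squares over all response columns jointly explained by the
    least-squares fit, adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-k-1) and
    F = (SS_fit / k) / (SS_res / (n-k-1)) with k predictors.
    """
    Yt = np.asarray(Yt, dtype=float)
    Xsub = np.asarray(Xsub, dtype=float)
    if Xsub.ndim == 1:
        Xsub = Xsub[:, None]
    n = Yt.shape[0]
    k = Xsub.shape[1]
    if k == 0:
        return 0.0, 0.0, float("nan")
    if n - k - 1 <= 0:
        raise ValueError(f"too many predictors: n={n}, k={k}")
    Ytc = _center(Yt)
    ss_total = float((Ytc * Ytc).sum())
    if ss_total == 0.0:
        raise ValueError("constant response: total sum of squares is zero")
    q = _orthonormal_columns(_center(Xsub))
    proj = q.T @ Ytc
    ss_fit = float((proj * proj).sum())
    r2 = ss_fit / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    f = (ss_fit / k) / ((ss_total - ss_fit) / (n - k - 1))
    return r2, adj, f


def _perm_matrix(rng: np.random.Generator, nperm: int, n: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(nperm)])


def _all_permutations(n: int) -> np.ndarray:
    import itertools
    import math

    if math.factorial(n) > 50_000:
        raise ValueError("exhaustive enumeration is limited to small n")
    return np.array(list(itertools.permutations(range(n))))


def _global_perm_f(Ytc, q, perms) -> np.ndarray:
    """Pseudo-F of the full model for row-permuted responses (vectorised)."""
    n, k = q.shape
    nperm = perms.shape[0]
    ss_total = (Ytc * Ytc).sum()
    inv = np.argsort(perms, axis=1)
    # (Q' Y[perm])_{aj} = sum_t Q[inv[t], a] Y[t, j]
    qg = q[inv]  # (nperm, n, k)
    proj = np.einsum("pnk,nr->pkr", qg, Ytc, optimize=True)
    ss_fit = (proj * proj).sum(axis=(1, 2))
    return (ss_fit / k) / ((ss_total - ss_fit) / (n - k - 1))


def _partial_perm_f(fitted, resid, q, c_perp, perms) -> np.ndarray:
    """Partial pseudo-F of one candidate under residual permutation."""
    n = fitted.shape[0]
    k = q.shape[1]
    nperm = perms.shape[0]
    A = np.hstack([q, c_perp[:, None]]).T  # (k+1, n)
    inv = np.argsort(perms, axis=1)
    Ag = A[:, inv]  # (k+1, nperm, n)
    M = np.einsum("apn,nr->apr", Ag, resid, optimize=True)
    base = (A @ fitted)[:, None, :]  # projections of the fixed part
    M = M + base
    ss_q = (M[:k] ** 2).sum(axis=(0, 2))
    d_ss = (M[k] ** 2).sum(axis=1)
    ss_rr = (resid * resid).sum()
    ss_ff = (fitted * fitted).sum()
    cross = fitted @ resid.T  # (n, n)
    tr = cross[np.arange(n)[None, :], perms].sum(axis=1)
    ss_total = ss_ff + ss_rr + 2.0 * tr
    ss_res = np.maximum(ss_total - ss_q - d_ss, 1e-300)
    return d_ss / (ss_res / (n - k - 2))


def permutation_pvalue(
    Yt: np.ndarray,
    Xselected: np.ndarray,
    candidate: np.ndarray | None,
    cfg: SelectionConfig,
    rng: np.random.Generator,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for the global or a sequential (partial) test.

    With ``candidate=None`` the global test permutes whole rows of the
    (centred) response and recomputes the pseudo-F of the model Xselected.
    Otherwise the candidate's partial F given Xselected is tested by
    permuting the residuals of the reduced model (the model containing only
    the already-selected variables). Both use
    p = (1 + #{F_perm >= F_obs}) / (1 + nperm) for random permutations;
    with ``exhaustive=True`` all n! row permutations are enumerated
    (identity included on both sides of the ratio), giving the exact
    permutation p-value for small n.
    """
    Yt = np.asarray(Yt, dtype=float)
    n = Yt.shape[0]
    Ytc = _center(Yt)
    Xsel = np.asarray(Xselected, dtype=float)
    if Xsel.ndim == 1:
        Xsel = Xsel[:, None]
    if exhaustive:
        perms = _all_permutations(n)
        denom = len(perms)
        num_base = 0
    else:
        perms = _perm_matrix(rng, cfg.nperm, n)
        denom = 1 + cfg.nperm
        num_base = 1
    ss_total = (Ytc * Ytc).sum()
    if candidate is None:
        _, _, f_obs = rda_stats(Yt, Xsel)
        q = _orthonormal_columns(_center(Xsel))
        if not np.isfinite(f_obs):
            warnings.warn("zero residual variance in global test", stacklevel=2)
            return 1.0 / denom
        f_perm = _global_perm_f(Ytc, q, perms)
        return float((num_base + (f_perm >= f_obs - 1e-12).sum()) / denom)
    c = np.asarray(candidate, dtype=float).ravel()
    q = _orthonormal_columns(_center(Xsel)) if Xsel.shape[1] else np.empty((n, 0))
    k = q.shape[1]
    if n - k - 2 <= 0:
        raise ValueError("no residual degrees of freedom for the partial test")
    fitted = q @ (q.T @ Ytc)
    resid = Ytc - fitted
    cc = _center(c)
    c_perp = cc - q @ (q.T @ cc)
    norm = np.linalg.norm(c_perp)
    if norm <= _RANK_TOL * max(np.linalg.norm(cc), 1.0):
        raise ValueError("candidate is collinear with the selected variables")
    c_perp = c_perp / norm
    d_ss = float(((c_perp @ Ytc) ** 2).sum())
    ss_q = float(((q.T @ Ytc) ** 2).sum())
    ss_res = ss_total - ss_q - d_ss
    if ss_res <= 1e-12 * ss_total:
        warnings.warn("zero residual variance in partial test", stacklevel=2)
        return 1.0 / denom
    f_obs = d_ss / (ss_res / (n - k - 2))
    f_perm = _partial_perm_f(fitted, resid, q, c_perp, perms)
    return float((num_base + (f_perm >= f_obs - 1e-12).sum()) / denom)


def _strip_intercept(X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Drop a leading all-constant column (design-matrix intercept)."""
    if X.shape[1] and np.allclose(X[:, 0], X[0, 0]):
        return X[:, 1:], True
    return X, False


def forward_select_rda(
    Yt: np.ndarray,
    X: np.ndarray,
    cfg: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Forward selection of RDA predictors under the double stopping rule.

    ``Yt`` is the (already transformed) community matrix, ``X`` the
    predictor matrix (a leading intercept column, if present, is ignored —
    RDA handles the intercept by centring). Returns the ordered selection,
    per-step statistics, and the adjusted R^2 of the accepted model as
    ``coef_det``. Variable indices are 1-based.
    """
    cfg = cfg or SelectionConfig()
    rng = rng if rng is not None else np.random.default_rng()
    Yt = np.asarray(Yt, dtype=float)
    X, _ = _strip_intercept(np.asarray(X, dtype=float))
    n, m = X.shape
    if m > n - 2:
        raise ValueError(f"m={m} predictors need at least n={m + 2} sites")
    Ytc = reduce_response(_center(Yt))
    _, adj_global, _ = rda_stats(Ytc, X)
    p_global = permutation_pvalue(Ytc, X, None, cfg, rng)
    if p_global > cfg.alpha:
        return SelectionResult(
            method="RDA/FW",
            selected=(),
            stop_reason="global",
            coef_det=0.0,
            global_adj_r2=adj_global,
            global_p=p_global,
        )
    Xc = _center(X)
    ss_total = float((Ytc * Ytc).sum())
    selected: list[int] = []
    steps: list[dict] = []
    q = np.empty((n, 0))
    ss_fit = 0.0
    adj_current = 0.0
    stop_reason = "exhausted"
    remaining = list(range(m))
    while remaining:
        k = len(selected)
        if n - k - 2 < 1:
            stop_reason = "df"
            break
        # rank candidates by adjusted R^2 of the augmented model
        best = None
        for j in remaining:
            cj = Xc[:, j]
            c_perp = cj - q @ (q.T @ cj)
            norm = np.linalg.norm(c_perp)
            if norm <= _RANK_TOL * max(np.linalg.norm(cj), 1.0):
                continue  # collinear with current model
            gain = float((((c_perp / norm) @ Ytc) ** 2).sum())
            r2_aug = (ss_fit + gain) / ss_total
            adj_aug = 1.0 - (1.0 - r2_aug) * (n - 1) / (n - k - 2)
            if best is None or adj_aug > best[1] + 1e-15:
                best = (j, adj_aug, r2_aug, c_perp / norm)
        if best is None:
            stop_reason = "collinear"
            break
        j, adj_aug, r2_aug, c_dir = best
        if adj_aug > adj_global:
            steps.append(
                {"candidate": j + 1, "r2": r2_aug, "adj_r2": adj_aug,
                 "F": np.nan, "p": np.nan, "accepted": False}
            )
            stop_reason = "adjr2"
            break
        p_val = permutation_pvalue(Ytc, q, Xc[:, j], cfg, rng)
        d_ss = float(((c_dir @ Ytc) ** 2).sum())
        ss_res = ss_total - ss_fit - d_ss
        f_partial = d_ss / (ss_res / (n - k - 2)) if ss_res > 0 else np.inf
        accepted = p_val <= cfg.alpha
        steps.append(
            {"candidate": j + 1, "r2": r2_aug, "adj_r2": adj_aug,
             "F": f_partial, "p": p_val, "accepted": accepted}
        )
        if not accepted:
            stop_reason = "alpha"
            break
        selected.append(j)
        remaining.remove(j)
        q = np.hstack([q, c_dir[:, None]])
        ss_fit += d_ss
        adj_current = adj_aug
    return SelectionResult(
        method="RDA/FW",
        selected=tuple(j + 1 for j in selected),
        steps=steps,
        stop_reason=stop_reason,
        coef_det=adj_current,
        global_adj_r2=adj_global,
        global_p=p_global,
    )
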