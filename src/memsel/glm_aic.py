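"""Multispecies binomial GLM selection by summed AIC, plus the D-value.

Each species gets its own logistic regression on a shared predictor
subset; the model-selection score is the AIC summed over species, with
(|subset| + 1) parameters counted per species. Selection is greedy forward
search: starting from intercept-only models, the candidate whose addition
most lowers the summed AIC is added, until no candidate lowers it. The
companion fit summary is the D-value, a deviance-based coefficient of
determination pooled over species:
D = 1 - sum(residual deviance) / sum(null deviance).
"""

from __future__ import annotations

import numpy as np

from memsel._glm import BatchGlmFit, fit_logistic_batch
from memsel.rda_forward import SelectionResult

__all__ = ["total_aic", "forward_select_glm", "d_value"]

#: a candidate must lower the summed AIC by more than this to be accepted
AIC_TOL = 1e-8


def _design_subset(X: np.ndarray, subset) -> tuple[np.ndarray, np.ndarray]:
    """Columns [intercept] + subset of the full design (1-based indices)."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1] - 1
    idx = sorted(int(j) for j in subset)
    if any(not 1 <= j <= m for j in idx):
        raise ValueError(f"subset indices out of range 1..{m}: {idx}")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate indices in subset")
    cols = np.array([0] + idx, dtype=int)
    return X[:, cols], cols


def _fit_subset(
    Y: np.ndarray, X: np.ndarray, subset, beta0: np.ndarray | None = None
) -> BatchGlmFit:
    Xsub, _ = _design_subset(X, subset)
    n = Xsub.shape[0]
    if Xsub.shape[1] > n - 1:
        raise ValueError("more parameters than sites")
    return fit_logistic_batch(Xsub, Y, beta0=beta0)


def total_aic(Y: np.ndarray, X: np.ndarray, subset) -> float:
    """Summed AIC over species of logistic fits on intercept + subset."""
    return float(_fit_subset(Y, X, subset).aic().sum())


def d_value(Y: np.ndarray, X: np.ndarray, subset) -> float:
    """Pooled deviance-based coefficient of determination.

    D = 1 - (sum of residual deviances) / (sum of null deviances), with
    sums over species. Errors if every species is constant (pooled null
    deviance zero).
    """
    fit = _fit_subset(Y, X, subset)
    null = fit_logistic_batch(np.ones((np.asarray(X).shape[0], 1)), Y)
    pooled_null = float(null.deviance.sum())
    # capped fits leave a ~1e-12 remnant even for constant species
    if pooled_null <= 1e-8:
        raise ValueError("all species constant: pooled null deviance is zero")
    return 1.0 - float(fit.deviance.sum()) / pooled_null


def forward_select_glm(
    Y: np.ndarray,
    X: np.ndarray,
    tol: float = AIC_TOL,
    max_vars: int | None = None,
) -> SelectionResult:
    """Greedy forward selection minimising the summed AIC.

    At each step every remaining candidate is scored by the summed AIC of
    the augmented model (fits warm-started from the current model); the
    minimiser is added if it lowers the total by more than ``tol``, with
    exact ties broken by the lowest index. ``coef_det`` of the result is
    the D-value of the accepted model. Indices are 1-based.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    n, m1 = X.shape
    m = m1 - 1
    if m < 1:
        raise ValueError("need at least one candidate predictor")
    limit = m if max_vars is None else min(m, max_vars)
    current_fit = _fit_subset(Y, X, ())
    current_aic = float(current_fit.aic().sum())
    selected: list[int] = []
    steps: list[dict] = [
        {"step": 0, "candidate": 0, "total_aic": current_aic, "accepted": True}
    ]
    remaining = list(range(1, m + 1))
    stop_reason = "exhausted"
    while remaining and len(selected) < limit:
        if len(selected) + 2 > n - 1:
            stop_reason = "df"
            break
        p = Y.shape[1] if Y.ndim == 2 else 1
        best_j, best_aic, best_fit = None, np.inf, None
        # warm start: current coefficients plus a zero row for the candidate
        for j in remaining:
            subset = sorted(selected + [j])
            pos = subset.index(j) + 1  # +1 for intercept row
            beta0 = np.insert(current_fit.coef, pos, 0.0, axis=0)
            fit = _fit_subset(Y, X, subset, beta0=beta0)
            aic = float(fit.aic().sum())
            if aic < best_aic - 1e-12:  # strict: ties keep the lower index
                best_j, best_aic, best_fit = j, aic, fit
        improvement = current_aic - best_aic
        steps.append(
            {
                "step": len(selected) + 1,
                "candidate": best_j,
                "total_aic": best_aic,
                "accepted": improvement > tol,
            }
        )
        if improvement <= tol:
            stop_reason = "aic"
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current_fit, current_aic = best_fit, best_aic
    try:
        dval = d_value(Y, X, selected)
    except ValueError:
        dval = float("nan")
    return SelectionResult(
        method="GLM/AIC",
        selected=tuple(selected),
        steps=steps,
        stop_reason=stop_reason,
        coef_det=dval,
    )
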