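"""Binary community simulation under two absence mechanisms.

Given a design matrix X and a scenario coefficient matrix C*, the linear
predictor Yhat = X C* is turned into presence/absence data in one of two
ways that differ in what an absence means:

* true absences (SPM): Yhat holds logit presence probabilities; each cell
  is Bernoulli(expit(yhat)).
* sampling absences (SAM): Yhat holds log expected abundances; a species
  is detected when a Poisson(lambda = exp(yhat)) draw is at least 1, which
  happens with probability 1 - exp(-lambda); each cell is Bernoulli of
  that detection probability.

The two mechanisms never share a probability map: the logistic and the
Poisson-detection curves cross but are nowhere equal.
"""

from __future__ import annotations

import numpy as np

from memsel.coefficient_model import CoefficientMatrix

__all__ = [
    "linear_predictor",
    "spm_probabilities",
    "sam_probabilities",
    "simulate_spm",
    "simulate_sam",
    "replicate_rng",
]

#: log-abundances above this would overflow exp() in double precision
_SAM_ETA_MAX = 700.0


def linear_predictor(X: np.ndarray, Cstar: CoefficientMatrix | np.ndarray) -> np.ndarray:
    """Yhat = X C*, the n x p matrix of linear predictors."""
    C = Cstar.coef if isinstance(Cstar, CoefficientMatrix) else np.asarray(Cstar)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != C.shape[0]:
        raise ValueError(
            f"design has {X.shape[1]} columns but coefficients have {C.shape[0]} rows"
        )
    yhat = X @ C
    if not np.isfinite(yhat).all():
        raise ValueError("non-finite linear predictor")
    return yhat


def spm_probabilities(yhat: np.ndarray) -> np.ndarray:
    """Presence probabilities under true absences: expit(yhat)."""
    return 1.0 / (1.0 + np.exp(-yhat))


def sam_probabilities(yhat: np.ndarray) -> np.ndarray:
    """Detection probabilities under Poisson sampling: 1 - exp(-exp(yhat))."""
    too_big = yhat > _SAM_ETA_MAX
    if too_big.any():
        i, j = np.argwhere(too_big)[0]
        raise ValueError(
            f"log abundance overflows exp() at site {i}, species {j}: {yhat[i, j]:.3g}"
        )
    lam = np.exp(yhat)
    return -np.expm1(-lam)


def simulate_spm(
    X: np.ndarray, Cstar: CoefficientMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate presence/absence with true absences (logistic Bernoulli)."""
    prob = spm_probabilities(linear_predictor(X, Cstar))
    return (rng.random(prob.shape) < prob).astype(np.int8)


def simulate_sam(
    X: np.ndarray, Cstar: CoefficientMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate presence/absence with sampling-induced absences.

    The linear predictor is read as log expected abundance; detection is
    Bernoulli(1 - exp(-lambda)).
    """
    prob = sam_probabilities(linear_predictor(X, Cstar))
    return (rng.random(prob.shape) < prob).astype(np.int8)


def replicate_rng(master_seed: int, *indices: int) -> np.random.Generator:
    """Independent, reproducible RNG substream for one replicate.

    Substreams are derived as SeedSequence(master_seed, spawn_key=indices),
    so every (scenario, mechanism, replicate, ...) tuple owns a stream that
    is independent of all others and recoverable in isolation.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=tuple(int(i) for i in indices))
    )
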