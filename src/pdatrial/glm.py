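"""Deterministic weighted logistic regression by Newton--Raphson.

The pooled-logistic fits of this package (daily treatment-initiation hazard,
daily extubation hazard) sit inside tight loops -- bootstrap replicates and
Monte-Carlo recovery studies -- so the solver is a compact dense IRLS on numpy
arrays rather than a full GLM framework.  It computes the exact maximum
likelihood estimate: the test suite cross-checks coefficients against
statsmodels GLM on the same data.

Columns are internally centred and scaled for conditioning; reported
coefficients are on the original scale.  The fit is deterministic: fixed start
at zero, step-halving line search, convergence on the Newton step norm.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "fit_logistic",
    "predict_proba",
    "sigmoid",
    "CollinearityError",
    "ConvergenceError",
    "SeparationError",
]


class CollinearityError(RuntimeError):
    """Design matrix is numerically singular (e.g. duplicated covariates)."""


class ConvergenceError(RuntimeError):
    """Newton iterations did not converge."""


class SeparationError(RuntimeError):
    """(Quasi-)complete separation: the MLE lies at infinity."""


def sigmoid(eta: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(eta, dtype=float)))


# |standardised coefficient| beyond which we declare separation: a log-odds of
# 30 per standard deviation is far outside anything estimable from finite data.
_SEPARATION_BOUND = 30.0


def _log_likelihood(eta, y, w):
    # log L = sum w * (y*eta - log(1+exp(eta))), computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    *,
    column_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-11,
) -> np.ndarray:
    """Fit a weighted logistic regression and return the coefficient vector.

    Parameters
    ----------
    X : (n, p) design matrix.  An intercept column of ones, if wanted, must be
        included explicitly (constant columns are detected and left unscaled).
    y : (n,) binary outcomes in {0, 1}.
    sample_weight : optional (n,) non-negative weights.
    column_names : used only to make error messages informative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    names = column_names or [f"x{j}" for j in range(p)]

    # Centre/scale non-constant columns for conditioning.
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    const = scale < 1e-12
    mean = np.where(const, 0.0, mean)
    scale = np.where(const, 1.0, scale)
    Xs = (X - mean) / scale

    beta = np.zeros(p)
    eta = Xs @ beta
    ll = _log_likelihood(eta, y, w)
    converged = False
    for _ in range(max_iter):
        mu = sigmoid(np.clip(eta, -35.0, 35.0))
        weight_ir = w * mu * (1.0 - mu)
        grad = Xs.T @ (w * (y - mu))
        hess = (Xs * weight_ir[:, None]).T @ Xs
        try:
            if p > 1:
                ev = np.linalg.eigvalsh(hess)
                if ev[0] <= 0 or ev[-1] / ev[0] > 1e12:
                    raise CollinearityError(
                        "singular or ill-conditioned information matrix; check "
                        f"for collinear covariates among {names}"
                    )
            cho = scipy.linalg.cho_factor(hess)
            step = scipy.linalg.cho_solve(cho, grad)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
            raise CollinearityError(
                "singular information matrix; check for collinear covariates "
                f"among {names}"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise CollinearityError(
                f"non-finite Newton step; check for collinear covariates among {names}"
            )
        # Step-halving line search keeps the iteration monotone (deterministic).
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            eta_c = Xs @ cand
            ll_c = _log_likelihood(eta_c, y, w)
            if ll_c >= ll - 1e-12:
                break
            factor *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise SeparationError(
                "perfect or quasi-perfect separation detected; consider pooling "
                "day strata or dropping covariates "
                f"(columns: {names})"
            )
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(n={n}, p={p}, events={float(np.sum(w * y)):.1f})"
        )

    # Back-transform to the original column scale.
    beta_orig = beta / scale
    # Constant columns absorb the centring offset (there is normally exactly
    # one: the intercept).  If several constant columns exist the offset is
    # attributed to the first.
    offset = -float(np.sum(beta * mean / scale))
    const_idx = np.where(const)[0]
    if const_idx.size:
        j = const_idx[0]
        col_val = X[0, j] if n else 1.0
        beta_orig[j] = beta_orig[j] + offset / (col_val if col_val != 0 else 1.0)
    elif abs(offset) > 1e-10:
        raise CollinearityError(
            "design matrix has no intercept column to absorb the centring offset"
        )
    return beta_orig


def predict_proba(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Predicted event probability under a fitted logistic model."""
    return sigmoid(np.asarray(X, float) @ np.asarray(beta, float))
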