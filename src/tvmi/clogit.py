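"""Conditional logistic regression over matched sets, from first principles.

Each matched set contributes one case day and 3-4 referent days.  With
linear predictor ``eta = X beta`` the conditional log-likelihood is

    sum over sets [ eta_case - log sum_{j in set} exp(eta_j) ],

the probability of picking the observed case day out of the set.  The
likelihood depends only on within-set contrasts of X: set-constant columns
are non-identifiable and rejected.  Optimisation is Newton-Raphson with
step-halving from beta = 0, with analytic gradient and Hessian and per-set
max-subtraction for numerical stability.  Optional per-set weights multiply
a set's contribution (used to collapse duplicated sets).

Inference downstream is Wald: covariance = inverse observed information at
the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FitResult",
    "NonIdentifiableError",
    "conditional_loglik",
    "fit",
]

_BETA_BOUND = 15.0  # |beta| beyond this signals separation / divergence
_MAX_HALVINGS = 30


class NonIdentifiableError(ValueError):
    """A design column has no within-set variation (or the Hessian is singular)."""


@dataclass
class FitResult:
    params: pd.Series  # beta, indexed by column name
    cov: pd.DataFrame  # inverse observed information
    loglik: float
    n_iter: int
    converged: bool
    n_sets: int
    n_dropped: int  # sets with no within-set variation in any column
    grad_norm: float = np.nan

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


def _prepare(table: pd.DataFrame, xcols: list[str]):
    """Sort by set, extract arrays, validate one case per set."""
    if table[xcols].isna().any().any() or not np.isfinite(
        table[xcols].to_numpy()
    ).all():
        raise ValueError("non-finite values in design columns")
    tab = table.sort_values("set_id", kind="stable")
    X = tab[xcols].to_numpy(float)
    y = tab["case"].to_numpy(int)
    sets = tab["set_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, sets[1:] != sets[:-1]])
    sizes = np.diff(np.r_[starts, len(sets)])
    if np.any(sizes < 2):
        raise ValueError("every matched set needs at least 2 rows")
    cases_per_set = np.add.reduceat(y, starts)
    if np.any(cases_per_set != 1):
        raise ValueError("every matched set needs exactly one case row")
    if "weight" in tab.columns:
        w_row = tab["weight"].to_numpy(float)
        w = w_row[starts]
        if not np.allclose(np.add.reduceat(w_row, starts), w * sizes):
            raise ValueError("weight must be constant within each set")
    else:
        w = np.ones(len(starts))
    return X, y, starts, sizes, w


def _loglik_parts(beta, X, y, starts, sizes, w):
    eta = X @ beta
    set_ids = np.repeat(np.arange(len(starts)), sizes)
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - m[set_ids])
    denom = np.add.reduceat(z, starts)
    lse = m + np.log(denom)
    p = z / denom[set_ids]

    ll = float(np.sum(w * (np.add.reduceat(eta * y, starts) - lse)))
    wp = w[set_ids] * p
    # gradient: sum_sets w * (x_case - E_p[x])
    grad = (w[set_ids] * y) @ X - wp @ X
    # Hessian: -sum_sets w * (E_p[x x'] - E_p[x] E_p[x]')
    M = np.empty((len(starts), X.shape[1]))
    for k in range(X.shape[1]):
        M[:, k] = np.add.reduceat(p * X[:, k], starts)
    hess = -(X.T @ (wp[:, None] * X) - (w[:, None] * M).T @ M)
    return ll, grad, hess


def conditional_loglik(beta, table: pd.DataFrame, xcols: list[str]):
    """Log-likelihood, gradient and Hessian at ``beta`` for a model table."""
    beta = np.asarray(beta, dtype=float)
    X, y, starts, sizes, w = _prepare(table, xcols)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]}")
    return _loglik_parts(beta, X, y, starts, sizes, w)


def _informative_mask(X, starts, sizes):
    """Per-set: does any column vary within the set?  Per-column: does the
    column vary within any set?"""
    set_ids = np.repeat(np.arange(len(starts)), sizes)
    lo = np.minimum.reduceat(X, starts)
    hi = np.maximum.reduceat(X, starts)
    ptp = hi - lo
    set_informative = (ptp > 0).any(axis=1)
    col_informative = (ptp > 0).any(axis=0)
    return set_informative, col_informative, set_ids


def fit(
    table: pd.DataFrame,
    xcols: list[str],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FitResult:
    """Maximise the conditional logistic likelihood by Newton-Raphson.

    Sets with no within-set variation in any design column contribute a
    constant to the likelihood; they are dropped and counted.  A column
    constant within every remaining set raises :class:`NonIdentifiableError`.
    Convergence: max-norm of the gradient below ``tol``.
    """
    X, y, starts, sizes, w = _prepare(table, xcols)
    set_inf, col_inf, set_ids = _informative_mask(X, starts, sizes)
    n_dropped = int((~set_inf).sum())
    if not set_inf.any():
        raise NonIdentifiableError("no informative strata (no within-set variation)")
    if n_dropped:
        keep_rows = set_inf[set_ids]
        X, y = X[keep_rows], y[keep_rows]
        w = w[set_inf]
        sizes = sizes[set_inf]
        starts = np.r_[0, np.cumsum(sizes)[:-1]]
        _, col_inf, _ = _informative_mask(X, starts, sizes)
    if not col_inf.all():
        bad = [xcols[k] for k in np.flatnonzero(~col_inf)]
        raise NonIdentifiableError(
            f"columns with no within-set variation are non-identifiable: {bad}"
        )

    K = X.shape[1]
    beta = np.zeros(K)
    ll, grad, hess = _loglik_parts(beta, X, y, starts, sizes, w)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            bad = _collinear_columns(X, xcols)
            raise NonIdentifiableError(
                f"singular Hessian; collinear design columns: {bad}"
            ) from None
        new_beta, new = beta + step, None
        # accept within rounding of the likelihood's own scale, else halve
        accept_tol = 1e-9 * (abs(ll) + 1.0)
        for _ in range(_MAX_HALVINGS):
            new = _loglik_parts(new_beta, X, y, starts, sizes, w)
            if new[0] > ll - accept_tol:
                break
            step = step / 2
            new_beta = beta + step
        else:
            break  # no uphill step found
        beta, (ll, grad, hess) = new_beta, new
        if np.max(np.abs(beta)) > _BETA_BOUND:
            break  # separation / divergence
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    if np.max(np.abs(beta)) > _BETA_BOUND:
        converged = False  # separation: the MLE ran away

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        bad = _collinear_columns(X, xcols)
        raise NonIdentifiableError(
            f"singular Hessian at optimum; collinear design columns: {bad}"
        ) from None
    cov = (cov + cov.T) / 2
    return FitResult(
        params=pd.Series(beta, index=xcols),
        cov=pd.DataFrame(cov, index=xcols, columns=xcols),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_sets=len(starts),
        n_dropped=n_dropped,
        grad_norm=float(np.max(np.abs(grad))),
    )


def _collinear_columns(X, xcols) -> list[str]:
    """Name columns implicated in a rank deficiency via pivoted QR."""
    Xc = X - X.mean(axis=0)
    _, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * 1e-10 if diag.max() > 0 else 1.0
    return [xcols[k] for k in np.flatnonzero(diag < thresh)]
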