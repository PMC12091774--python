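"""Exposure-lag crossbasis: threshold hinges crossed with a natural cubic lag spline.

The distributed-lag model used throughout this package couples a two-sided
threshold ("hockey-stick") function in the exposure dimension — an upward
hinge ``max(x - thr, 0)`` and a downward hinge ``max(thr - x, 0)``, both with
unit slope so coefficients are per 1 °C — with a natural cubic spline over
integer lags 0..6.  The lag spline carries an intercept and two interior
knots placed at evenly spaced values on the log-lag scale, i.e. at
``L**(1/3)`` and ``L**(2/3)`` for maximum lag ``L`` (lag 0 being in range,
the knots are spaced evenly in ``log`` between lag ``L**0 = 1``'s log of 0
and ``log L``; this convention is documented in docs/methods.md).  With two
interior knots plus the intercept the lag basis has dimension 4, so the full
crossbasis has 2 x 4 = 8 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrossbasisSpec",
    "natural_spline_basis",
    "lag_basis",
    "threshold_pair",
    "build_crossbasis",
    "crossbasis_matrix",
    "add_crossbasis",
]


def natural_spline_basis(
    x: np.ndarray,
    interior_knots,
    boundary_knots,
    include_intercept: bool = False,
) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction).

    With knot sequence ``xi_1 < ... < xi_K`` (boundaries included) the basis
    is ``1, x, N_3, ..., N_K`` where ``N_{k+2} = d_k - d_{K-1}`` and
    ``d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)``.
    Every basis function is linear beyond the boundary knots (second
    derivative zero), which is the defining "natural" constraint.

    Returns an array of shape ``(len(x), K)`` with the intercept, or
    ``(len(x), K - 1)`` without it (the leading constant column dropped).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    knots = np.asarray(sorted([lo, *map(float, interior_knots), hi]))
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots.tolist()}")
    if np.any((np.asarray(interior_knots) <= lo) | (np.asarray(interior_knots) >= hi)):
        raise ValueError(
            f"interior knots {list(interior_knots)} must lie strictly inside "
            f"({lo}, {hi})"
        )
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    basis = np.column_stack(cols)
    return basis if include_intercept else basis[:, 1:]


@dataclass(frozen=True)
class CrossbasisSpec:
    """Definition of the threshold x lag-spline crossbasis.

    Parameters
    ----------
    threshold : hinge point on the exposure (temperature-variability) axis, °C.
    max_lag : largest lag in days; the lag range is 0..max_lag inclusive.
    interior_knots : lag positions of the interior spline knots; ``None``
        selects the evenly-spaced-log default ``max_lag**(k/(K+1))``, k=1..K
        with K = ``n_interior_knots``.
    n_interior_knots : number of interior knots when ``interior_knots`` is None.
    intercept : whether the lag basis carries an intercept column (default
        True, the usual crossbasis convention).
    """

    threshold: float = 0.0
    max_lag: int = 6
    interior_knots: tuple[float, ...] | None = None
    n_interior_knots: int = 2
    intercept: bool = True

    def lag_knots(self) -> np.ndarray:
        """Interior knot positions; default ``max_lag**(k/(K+1))``."""
        if self.interior_knots is not None:
            knots = np.asarray(self.interior_knots, dtype=float)
        else:
            K = self.n_interior_knots
            knots = self.max_lag ** (np.arange(1, K + 1) / (K + 1))
        if np.any((knots <= 0) | (knots >= self.max_lag)):
            raise ValueError(
                f"interior lag knots {knots.tolist()} must lie strictly inside "
                f"(0, {self.max_lag})"
            )
        if np.any(np.diff(knots) <= 0):
            raise ValueError("interior lag knots must be strictly increasing")
        return knots

    @property
    def n_lag(self) -> int:
        return self.max_lag + 1

    @property
    def lag_dim(self) -> int:
        return len(self.lag_knots()) + 1 + (1 if self.intercept else 0)

    @property
    def n_columns(self) -> int:
        return 2 * self.lag_dim

    def column_names(self) -> list[str]:
        k = self.lag_dim
        return [f"cb_up_{j}" for j in range(1, k + 1)] + [
            f"cb_dn_{j}" for j in range(1, k + 1)
        ]


def lag_basis(spec: CrossbasisSpec) -> np.ndarray:
    """Lag-spline basis evaluated at integer lags 0..max_lag.

    Shape ``(max_lag + 1, lag_dim)``; with the defaults, ``(7, 4)``.
    """
    lags = np.arange(spec.n_lag, dtype=float)
    return natural_spline_basis(
        lags,
        spec.lag_knots(),
        (0.0, float(spec.max_lag)),
        include_intercept=spec.intercept,
    )


def threshold_pair(x, threshold: float = 0.0):
    """Two-sided unit-slope hinge: ``(max(x - thr, 0), max(thr - x, 0))``.

    Both components are nonnegative; the downward component measures °C
    *below* the threshold, so downward effects read per 1 °C decrease.
    """
    x = np.asarray(x, dtype=float)
    up = np.maximum(x - threshold, 0.0)
    down = np.maximum(threshold - x, 0.0)
    return up, down


def build_crossbasis(tv_by_lag, spec: CrossbasisSpec) -> np.ndarray:
    """Crossbasis row for one day's lagged exposure history.

    ``tv_by_lag`` holds temperature variability at lags 0..max_lag.  Entry
    (direction d, basis index k) is ``sum_l b_d(tv_l) * g_k(l)`` — the plain
    tensor contraction, no normalisation.
    """
    tv = np.asarray(tv_by_lag, dtype=float)
    if tv.shape != (spec.n_lag,):
        raise ValueError(f"expected {spec.n_lag} lagged values, got shape {tv.shape}")
    bad = np.flatnonzero(~np.isfinite(tv))
    if bad.size:
        raise ValueError(f"missing exposure at lag {bad[0]}")
    up, down = threshold_pair(tv, spec.threshold)
    G = lag_basis(spec)
    return np.concatenate([up @ G, down @ G])


def crossbasis_matrix(tv_matrix, spec: CrossbasisSpec) -> pd.DataFrame:
    """Vectorised crossbasis for many days: (n, n_lag) -> (n, 2 * lag_dim)."""
    tv = np.asarray(tv_matrix, dtype=float)
    if tv.ndim != 2 or tv.shape[1] != spec.n_lag:
        raise ValueError(f"expected (n, {spec.n_lag}) exposure histories")
    if not np.all(np.isfinite(tv)):
        r, c = np.argwhere(~np.isfinite(tv))[0]
        raise ValueError(f"missing exposure in row {r} at lag {c}")
    up, down = threshold_pair(tv, spec.threshold)
    G = lag_basis(spec)
    return pd.DataFrame(
        np.hstack([up @ G, down @ G]), columns=spec.column_names()
    )


def add_crossbasis(table: pd.DataFrame, spec: CrossbasisSpec) -> pd.DataFrame:
    """Append crossbasis columns to a model table carrying tv_lag0..tv_lagL."""
    tv_cols = [f"tv_lag{l}" for l in range(spec.n_lag)]
    missing = [c for c in tv_cols if c not in table.columns]
    if missing:
        raise ValueError(f"model table lacks lagged exposure columns {missing}")
    cb = crossbasis_matrix(table[tv_cols].to_numpy(), spec)
    cb.index = table.index
    return pd.concat([table, cb], axis=1)
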