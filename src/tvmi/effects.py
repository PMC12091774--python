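"""Lag-specific odds ratios, subgroup analyses and effect modification.

A fitted crossbasis coefficient vector is turned into lag-specific log-odds
ratios by the contrast ``c`` whose entries are the lag-basis values
``g_k(lag)`` on the chosen direction's columns and zero elsewhere; because
the exposure hinges have unit slope the contrast reads per 1 °C of upward
(or downward) shift.  Standard errors follow from the delta method,
``se = sqrt(c' Sigma c)``; confidence intervals and p-values are Wald.

Effect modification enters as crossbasis-by-indicator interaction columns in
a single joint fit; the between-level difference at a focal lag is tested
with ``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` against the standard normal.
By convention upward effects are summarised at lag 0 and downward effects at
lag 2 (the lags where the associations peak); this is a reporting default,
not an inferential choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import clogit
from .crossbasis import CrossbasisSpec, add_crossbasis, lag_basis

__all__ = [
    "LagEffect",
    "ModifierResult",
    "lag_effect",
    "all_lag_effects",
    "run_analysis",
    "modifier_z",
    "modifier_analysis",
    "median_split",
]

FOCAL_LAG = {"up": 0, "down": 2}  # reporting defaults


@dataclass
class LagEffect:
    direction: str  # "up" (per +1 °C) or "down" (per -1 °C)
    lag: int
    logor: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    contrast: np.ndarray


@dataclass
class ModifierResult:
    modifier: str
    direction: str
    lag: int
    effect_level0: LagEffect
    effect_level1: LagEffect
    z: float
    p: float


def _contrast(spec: CrossbasisSpec, direction: str, lag: int) -> np.ndarray:
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if not 0 <= lag <= spec.max_lag:
        raise ValueError(f"lag must be in 0..{spec.max_lag}")
    G = lag_basis(spec)
    k = spec.lag_dim
    c = np.zeros(2 * k)
    offset = 0 if direction == "up" else k
    c[offset : offset + k] = G[lag]
    return c


def _wald(logor: float, se: float) -> tuple[float, float, float, float]:
    or_ = float(np.exp(logor))
    lo = float(np.exp(logor - 1.959963984540054 * se))
    hi = float(np.exp(logor + 1.959963984540054 * se))
    p = float(2 * stats.norm.sf(abs(logor) / se)) if se > 0 else (1.0 if logor == 0 else 0.0)
    return or_, lo, hi, p


def lag_effect(
    fit: clogit.FitResult, spec: CrossbasisSpec, direction: str, lag: int
) -> LagEffect:
    """Per-1 °C odds ratio for one direction and single-day lag."""
    if not fit.converged:
        raise ValueError("refusing to summarise a non-converged fit")
    c_cb = _contrast(spec, direction, lag)
    cols = spec.column_names()
    c = pd.Series(0.0, index=fit.params.index)
    c[cols] = c_cb
    logor = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov @ c))
    or_, lo, hi, p = _wald(logor, se)
    return LagEffect(direction, lag, logor, se, or_, lo, hi, p, c.to_numpy())


def all_lag_effects(fit: clogit.FitResult, spec: CrossbasisSpec) -> pd.DataFrame:
    """The 2 x (max_lag + 1) grid of single-day lag effects as a tidy frame."""
    rows = []
    for direction in ("up", "down"):
        for lag in range(spec.n_lag):
            e = lag_effect(fit, spec, direction, lag)
            rows.append(
                {
                    "direction": direction,
                    "lag": lag,
                    "logor": e.logor,
                    "se": e.se,
                    "or": e.odds_ratio,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                }
            )
    return pd.DataFrame(rows)


def run_analysis(
    events: pd.DataFrame,
    exposures: pd.DataFrame,
    spec: CrossbasisSpec,
    subtype: str | None = None,
    subgroup: pd.Series | None = None,
    adjusters: pd.DataFrame | None = None,
    adjuster_cols: list[str] | None = None,
    label: str = "base",
) -> pd.DataFrame | None:
    """One full analysis: filter events, build sets, fit, extract 14 effects.

    ``subtype`` filters on the events' subtype column ("STEMI"/"NSTEMI";
    None or "total" keeps all).  ``subgroup`` is an optional boolean mask
    aligned with ``events``.  Returns None (with nothing fitted) for an
    empty subset.
    """
    from .design import build_matched_sets

    sel = events
    if subtype not in (None, "total"):
        sel = sel[sel["subtype"] == subtype]
    if subgroup is not None:
        sel = sel[subgroup.reindex(sel.index, fill_value=False)]
    if len(sel) == 0:
        return None
    table, _ = build_matched_sets(sel, exposures, adjusters)
    if len(table) == 0:
        return None
    table = add_crossbasis(table, spec)
    xcols = spec.column_names() + (adjuster_cols or [])
    res = clogit.fit(table, xcols)
    out = all_lag_effects(res, spec)
    out.insert(0, "analysis", label)
    out["n_sets"] = res.n_sets
    return out


def modifier_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sample z for a difference of independent log-OR estimates."""
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def modifier_analysis(
    table: pd.DataFrame,
    modifier: str,
    spec: CrossbasisSpec,
    direction: str | None = None,
    lag: int | None = None,
) -> ModifierResult:
    """Joint fit with crossbasis-by-modifier interactions and the focal-lag z-test.

    ``table`` is a model table already carrying crossbasis columns and a 0/1
    ``modifier`` column constant within each matched set.  Level-specific
    effects are the main-effect contrast (level 0) and main + interaction
    (level 1).
    """
    if direction is None:
        direction = "up"
    if lag is None:
        lag = FOCAL_LAG[direction]
    levels = table.groupby("set_id")[modifier].first()
    if levels.nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant; no contrast to test")
    cols = spec.column_names()
    icols = [f"{c}:{modifier}" for c in cols]
    tab = table.copy()
    ind = tab[modifier].to_numpy(float)
    for c, ic in zip(cols, icols):
        tab[ic] = tab[c].to_numpy() * ind
    res = clogit.fit(tab, cols + icols)

    c_cb = _contrast(spec, direction, lag)
    k = len(cols)

    def level_effect(level: int) -> LagEffect:
        c = pd.Series(0.0, index=res.params.index)
        c[cols] = c_cb
        if level == 1:
            c[icols] = c_cb
        logor = float(c @ res.params)
        se = float(np.sqrt(c @ res.cov @ c))
        or_, lo, hi, p = _wald(logor, se)
        return LagEffect(direction, lag, logor, se, or_, lo, hi, p, c.to_numpy())

    e0, e1 = level_effect(0), level_effect(1)
    z, p = modifier_z(e1.logor, e1.se, e0.logor, e0.se)
    return ModifierResult(modifier, direction, lag, e0, e1, z, p)


def median_split(values) -> np.ndarray:
    """0 = low (< median), 1 = high (>= median); ties at the median go high."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median split needs at least one value")
    return (v >= np.median(v)).astype(int)
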