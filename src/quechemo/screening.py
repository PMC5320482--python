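"""Plackett–Burman main-effect estimation and significance testing.

Main effects are tested against the pure-error standard deviation estimated
from replicated center points (the design's only genuine replicates), with a
two-sided t-test at 95 % confidence, and ranked as in a standardized Pareto
chart: bar length proportional to |t|, vertical line at the critical t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "EffectTable",
    "InsufficientReplicationError",
    "main_effects",
    "pure_error",
    "test_effects",
    "pareto_rank",
]


class InsufficientReplicationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectTable:
    """Per-factor main effects with t-test results against pure error.

    ``table`` columns: effect, standard_error, t_value, p_value, significant,
    sign.  When ``s_pe`` is zero the test is degenerate: t/p are NaN and
    ``significant`` is pandas NA.
    """

    table: pd.DataFrame
    s_pe: float
    df_pe: int
    t_critical: float
    alpha: float = 0.05

    @property
    def degenerate(self) -> bool:
        return self.s_pe == 0.0


def main_effects(design: DesignMatrix, responses) -> pd.Series:
    """effect_j = mean(y | X_j = +1) - mean(y | X_j = -1), center rows excluded."""
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError(
            f"responses length {y.shape[0]} does not match design rows {design.n_runs}"
        )
    if np.isnan(y).any():
        raise ValueError("missing response value")
    keep = ~design.is_center
    X = design.coded[keep]
    yk = y[keep]
    eff = {}
    for j, name in enumerate(design.factor_names):
        hi = X[:, j] > 0
        lo = X[:, j] < 0
        eff[name] = yk[hi].mean() - yk[lo].mean()
    return pd.Series(eff, name="effect")


def pure_error(center_responses) -> tuple[float, int]:
    """Sample SD of the center-point replicates and its degrees of freedom."""
    y = np.asarray(center_responses, dtype=float)
    if y.size < 2:
        raise InsufficientReplicationError(
            f"pure error needs >= 2 center responses, got {y.size}"
        )
    return float(np.std(y, ddof=1)), int(y.size - 1)


def test_effects(
    effects: pd.Series,
    s_pe: float,
    df_pe: int,
    alpha: float = 0.05,
    n_plus: int = 6,
    n_minus: int = 6,
) -> EffectTable:
    """t-test each main effect against pure error.

    SE(effect) = s_pe * sqrt(1/n+ + 1/n-); for the 12-run design both group
    sizes are 6.  With ``s_pe == 0`` significance is undefined and the table
    is flagged degenerate.
    """
    if s_pe < 0:
        raise ValueError("s_pe must be >= 0")
    if df_pe < 1:
        raise ValueError("df_pe must be >= 1")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_pe))
    se = s_pe * np.sqrt(1.0 / n_plus + 1.0 / n_minus)
    eff = effects.astype(float)
    if s_pe == 0.0:
        t = pd.Series(np.nan, index=eff.index)
        p = pd.Series(np.nan, index=eff.index)
        sig = pd.Series(pd.NA, index=eff.index, dtype="boolean")
    else:
        t = eff / se
        p = pd.Series(2.0 * stats.t.sf(np.abs(t), df_pe), index=eff.index)
        sig = pd.Series(np.abs(t) > t_crit, index=eff.index, dtype="boolean")
    table = pd.DataFrame(
        {
            "effect": eff,
            "standard_error": se,
            "t_value": t,
            "p_value": p,
            "significant": sig,
            "sign": np.where(eff >= 0, "+", "-"),
        }
    )
    return EffectTable(table=table, s_pe=float(s_pe), df_pe=int(df_pe),
                       t_critical=t_crit, alpha=alpha)


def idle_column_error(design: DesignMatrix, responses) -> tuple[float, int]:
    """Alternative error estimate from the idle (dummy) columns.

    With k < 11 factors the remaining 11 - k columns of the 12-run matrix
    estimate no real effect; their apparent effects are pure noise with
    variance sigma^2 * (1/6 + 1/6).  Returns an (s, df) pair on the same
    scale as :func:`pure_error`.  Off by default in the workflow — pure
    error from center points is the primary error term.
    """
    from .designs import PB12_GENERATOR

    k = design.n_factors
    if k >= 11:
        raise ValueError("no idle columns: design uses all 11 columns")
    y = np.asarray(responses, dtype=float)
    keep = ~design.is_center
    yk = y[keep]
    rows = [np.roll(PB12_GENERATOR, shift) for shift in range(11)]
    rows.append(-np.ones(11))
    full = np.vstack(rows)
    idle = full[:, k:]
    effects = (yk @ idle) / 6.0
    # Var(effect) = sigma^2 / 3 under the null
    s = float(np.sqrt(np.mean(effects**2) * 3.0))
    return s, idle.shape[1]


def pareto_rank(table: EffectTable) -> pd.DataFrame:
    """Factors sorted by |t| descending (ties keep input order), with the
    95 % threshold line attached as the ``t_critical`` attribute column."""
    df = table.table.copy()
    df["abs_t"] = df["t_value"].abs()
    # mergesort is stable -> ties broken by input factor order
    out = df.sort_values("abs_t", ascending=False, kind="mergesort")
    out["threshold"] = table.t_critical
    return out
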