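"""SANCO-style validation computations for a multi-residue LC-MS/MS method.

Covers linear calibration, matrix-effect quantification from calibration
slopes and its none/medium/strong classification, the effect of 10-fold
dilution, spiked-recovery summaries (intra/inter-day RSD), validation-based
LOQ selection, 2002/657/EC identification points, and monitoring-survey
aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "MatrixEffectResult",
    "RecoveryResult",
    "fit_calibration",
    "matrix_effect",
    "classify_me",
    "dilution_improvement",
    "recovery_summary",
    "summarize_recovery_table",
    "check_loq",
    "identification_points",
    "survey_summary",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reporting convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CalibrationCurve:
    """Unweighted OLS calibration line: signal = slope * conc + intercept.

    ``matrix == 'methanol'`` denotes the pure-solvent curve; ``dilution`` is
    'ND' (no dilution) or 'D10' (10-fold).  ``residual_sd``, ``x_mean`` and
    ``sxx`` feed the calibration term of the uncertainty budget.
    """

    slope: float
    intercept: float
    r_squared: float
    analyte: str = ""
    matrix: str = "methanol"
    dilution: str = "ND"
    levels: tuple[float, ...] = ()
    n: int = 0
    residual_sd: float = float("nan")
    x_mean: float = float("nan")
    sxx: float = float("nan")

    @property
    def usable(self) -> bool:
        return self.slope != 0.0


@dataclass(frozen=True)
class MatrixEffectResult:
    """ME (%) = (slope_matrix / slope_solvent - 1) * 100."""

    me_percent: float
    category: str
    direction: str

    @property
    def me_rounded(self) -> int:
        return int(round_half_away(self.me_percent))


@dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    matrix: str
    spike_level: str
    mean_recovery: float
    rsd_intra: float
    rsd_inter: float
    n_intra: int = 5
    n_inter: int = 15


def fit_calibration(
    levels,
    signals,
    analyte: str = "",
    matrix: str = "methanol",
    dilution: str = "ND",
    weighting: str = "none",
) -> CalibrationCurve:
    """Calibration line over >= 5 levels.

    Unweighted OLS by default; ``weighting='1/x'`` fits weighted least
    squares with weights proportional to 1/concentration.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size < 5:
        raise ValueError(f"calibration needs >= 5 levels, got {x.size}")
    if x.size != y.size:
        raise ValueError("levels and signals must be the same length")
    if not np.all(np.diff(x) > 0):
        raise ValueError("calibration levels must be strictly increasing")
    if weighting == "none":
        res = stats.linregress(x, y)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires positive levels")
        w = 1.0 / x
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        yw = np.average(y, weights=w)
        ss_tot = np.sum(w * (y - yw) ** 2)
        ss_res = np.sum(w * (y - (slope * x + intercept)) ** 2)
        r = np.sqrt(max(1.0 - ss_res / ss_tot, 0.0)) if ss_tot > 0 else 0.0

        class _Res:  # minimal linregress-compatible shim
            pass

        res = _Res()
        res.slope, res.intercept, res.rvalue = slope, intercept, r
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt((resid**2).sum() / (x.size - 2)))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        analyte=analyte,
        matrix=matrix,
        dilution=dilution,
        levels=tuple(x),
        n=int(x.size),
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
    )


def classify_me(me_percent: float) -> str:
    """none for -20..20 (inclusive), strong strictly beyond +/-50, else medium."""
    if -20.0 <= me_percent <= 20.0:
        return "none"
    if me_percent < -50.0 or me_percent > 50.0:
        return "strong"
    return "medium"


def matrix_effect(
    curve_matrix: CalibrationCurve, curve_solvent: CalibrationCurve
) -> MatrixEffectResult:
    """Percent slope deviation of the matrix-matched curve from solvent.

    Positive ME is ionization enhancement, negative is suppression.  Full
    precision is retained; display rounding is ``me_rounded``.
    """
    if curve_solvent.slope == 0.0:
        raise ZeroDivisionError("solvent calibration slope is zero")
    me = (curve_matrix.slope / curve_solvent.slope - 1.0) * 100.0
    direction = "suppression" if me < 0 else ("enhancement" if me > 0 else "neutral")
    return MatrixEffectResult(me_percent=me, category=classify_me(me), direction=direction)


def dilution_improvement(
    results_nd: dict[str, MatrixEffectResult],
    results_d10: dict[str, MatrixEffectResult],
    metric: str = "abs_decrease",
) -> float:
    """Percent of analytes in a matrix whose ME improved on 10-fold dilution.

    ``abs_decrease`` (default): share of analytes with |ME| strictly smaller
    after dilution.  ``strong_resolved``: share of ND-strong analytes that
    are no longer strong at D10 (NaN when nothing was strong).
    """
    if set(results_nd) != set(results_d10):
        raise ValueError("ND and D10 analyte sets differ")
    if metric == "abs_decrease":
        wins = [
            abs(results_d10[a].me_percent) < abs(results_nd[a].me_percent)
            for a in results_nd
        ]
        return 100.0 * sum(wins) / len(wins)
    if metric == "strong_resolved":
        strong = [a for a in results_nd if results_nd[a].category == "strong"]
        if not strong:
            return float("nan")
        resolved = [a for a in strong if results_d10[a].category != "strong"]
        return 100.0 * len(resolved) / len(strong)
    raise ValueError(f"unknown metric {metric!r}")


def recovery_summary(
    replicates: pd.DataFrame,
    analyte: str = "",
    matrix: str = "",
    spike_level: str = "",
    n_days: int = 3,
    n_reps: int = 5,
) -> RecoveryResult:
    """Mean recovery with intra-day (day 1, n=5) and inter-day (all 15) RSDs.

    ``replicates`` needs columns ``day``, ``rep``, ``recovery_pct`` with the
    full ``n_days x n_reps`` crossed structure.
    """
    df = replicates
    days = sorted(df["day"].unique())
    if len(days) != n_days:
        raise ValueError(f"expected {n_days} days, found {len(days)}: {days}")
    for d in days:
        cnt = (df["day"] == d).sum()
        if cnt != n_reps:
            raise ValueError(f"day {d} has {cnt} replicates, expected {n_reps}")
    all_vals = df["recovery_pct"].to_numpy(dtype=float)
    day1 = df.loc[df["day"] == days[0], "recovery_pct"].to_numpy(dtype=float)
    mean = float(all_vals.mean())
    rsd = lambda v: float(100.0 * np.std(v, ddof=1) / v.mean()) if v.mean() != 0 else 0.0
    return RecoveryResult(
        analyte=analyte, matrix=matrix, spike_level=spike_level,
        mean_recovery=mean,
        rsd_intra=rsd(day1),
        rsd_inter=rsd(all_vals),
        n_intra=n_reps, n_inter=n_days * n_reps,
    )


def summarize_recovery_table(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`recovery_summary` per analyte x matrix x level group."""
    rows = []
    for (a, m, lvl), grp in df.groupby(["analyte", "matrix", "level_label"], sort=False):
        r = recovery_summary(grp, analyte=a, matrix=m, spike_level=lvl, **kwargs)
        rows.append(
            dict(analyte=a, matrix=m, level_label=lvl,
                 mean_recovery=r.mean_recovery,
                 rsd_intra=r.rsd_intra, rsd_inter=r.rsd_inter)
        )
    return pd.DataFrame(rows)


def check_loq(
    candidate_levels,
    results_per_level: dict[float, list[RecoveryResult]],
) -> float | None:
    """Validation-based LOQ: the lowest spike level whose results all have
    mean recovery in [70, 120] % (inclusive) and every RSD < 20 % (strict).

    Returns None when no level passes (LOQ undefined)."""
    for level in sorted(candidate_levels):
        results = results_per_level.get(level)
        if not results:
            raise ValueError(f"no validation results at candidate level {level}")
        ok = all(
            70.0 <= r.mean_recovery <= 120.0
            and r.rsd_intra < 20.0
            and r.rsd_inter < 20.0
            for r in results
        )
        if ok:
            return float(level)
    return None


def identification_points(n_precursor: int, n_product: int) -> tuple[float, bool]:
    """2002/657/EC identification points: 1.0 per precursor + 1.5 per product
    ion; >= 4 IPs confirm an identification."""
    if n_precursor < 0 or n_product < 0:
        raise ValueError("ion counts must be >= 0")
    ips = 1.0 * n_precursor + 1.5 * n_product
    return ips, ips >= 4.0


def survey_summary(
    records: pd.DataFrame,
    loq: dict[str, float],
    commodity_counts: dict[str, int],
    mrl: pd.DataFrame | None = None,
) -> dict:
    """Aggregate a monitoring survey of real samples.

    ``records`` has one row per detection: sample_id, commodity, analyte,
    conc_ugkg (NaN = censored, below LOD).  A sample is positive when at
    least one analyte is quantified at or above its LOQ.  Ratios are
    reported as integer percent; an MRL table (analyte, commodity,
    mrl_mgkg) adds exceedance flags.
    """
    unknown = set(records["commodity"]) - set(commodity_counts)
    if unknown:
        raise ValueError(f"unknown commodity in records: {sorted(unknown)}")
    df = records.copy()
    df["conc_ugkg"] = pd.to_numeric(df["conc_ugkg"], errors="coerce")
    loq_for = df["analyte"].map(lambda a: loq.get(a, float("inf")))
    df["quantified"] = df["conc_ugkg"].notna() & (
        df["conc_ugkg"] >= loq_for.astype(float)
    )
    pos = df[df["quantified"]]
    per_commodity = {}
    for com, total in commodity_counts.items():
        n_pos = pos.loc[pos["commodity"] == com, "sample_id"].nunique()
        per_commodity[com] = {
            "n_samples": total,
            "n_positive": int(n_pos),
            "positive_pct": int(round_half_away(100.0 * n_pos / total)) if total else 0,
        }
    n_total = sum(commodity_counts.values())
    n_positive = pos["sample_id"].nunique()
    out: dict = {
        "per_commodity": per_commodity,
        "n_samples": n_total,
        "n_positive": int(n_positive),
        "positive_pct": int(round_half_away(100.0 * n_positive / n_total)) if n_total else 0,
    }
    if len(pos):
        imax = pos["conc_ugkg"].idxmax()
        out["max_concentration"] = {
            "conc_ugkg": float(pos.loc[imax, "conc_ugkg"]),
            "analyte": pos.loc[imax, "analyte"],
            "commodity": pos.loc[imax, "commodity"],
        }
    else:
        out["max_concentration"] = None
    if mrl is not None:
        merged = pos.merge(mrl, on=["analyte", "commodity"], how="left")
        exceed = merged[merged["conc_ugkg"] > merged["mrl_mgkg"] * 1000.0]
        out["mrl_exceedances"] = exceed[
            ["sample_id", "commodity", "analyte", "conc_ugkg"]
        ].to_dict("records")
    return out
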