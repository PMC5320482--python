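"""Human-readable markdown report over the pipeline's artifacts.

``build_report`` takes whatever stage artifacts exist and renders the
corresponding sections — calibration/matrix-effect table, recovery summary,
uncertainty budget, survey — skipping missing ones with a notice.  Output is
deterministic: identical inputs give byte-identical text.
"""

from __future__ import annotations

import pandas as pd

from .validation import round_half_away

__all__ = ["build_report"]

_ME_LEGEND = ("ME categories: none for -20..+20 %, strong beyond +/-50 %, "
              "medium otherwise.")


def _table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else floatfmt.format(v))
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def build_report(artifacts: dict) -> str:
    """Render a markdown summary from a dict of stage artifacts.

    Recognized keys: ``screening`` (DataFrame), ``optimum`` (Optimum),
    ``matrix_effects`` (DataFrame), ``recovery`` (DataFrame), ``budget``
    (DataFrame or list of UncertaintyBudget), ``survey`` (dict from
    survey_summary).
    """
    parts: list[str] = ["# Method optimization and validation report", ""]

    def section(title: str, key: str, renderer) -> None:
        parts.append(f"## {title}")
        if key not in artifacts or artifacts[key] is None:
            parts.append(f"_Section skipped: no `{key}` artifact provided._")
        else:
            renderer(artifacts[key])
        parts.append("")

    def r_screening(df):
        parts.append(_table(df))

    def r_optimum(opt):
        parts.append("Optimal extraction settings (coded units):")
        parts.append(_table(pd.DataFrame({
            "factor": list(opt.natural) if opt.natural else
            [f"x{i+1}" for i in range(len(opt.coded))],
            "coded": list(opt.coded),
            "natural": [opt.natural.get(k, float("nan")) for k in opt.natural]
            if opt.natural else [float("nan")] * len(opt.coded),
        })))
        parts.append("")
        parts.append(_table(pd.DataFrame({
            "analyte": list(opt.predictions),
            "predicted_recovery_pct": [opt.predictions[a] for a in opt.predictions],
            "d": [opt.d[a] for a in opt.predictions],
        })))
        parts.append("")
        parts.append(f"Overall desirability D = {opt.D:.3f}")

    def r_me(df):
        parts.append(_ME_LEGEND)
        parts.append("")
        parts.append(_table(df))

    def r_recovery(df):
        parts.append(_table(df))

    def r_budget(budget):
        if not isinstance(budget, pd.DataFrame):
            budget = pd.DataFrame([
                dict(analyte=b.analyte, u1=b.u1, u2=b.u2, u3=b.u3, u4=b.u4,
                     u_c=b.u_c_display, k=b.k, u_exp_percent=b.u_exp_display)
                for b in budget
            ])
        parts.append(_table(budget))
        if "u_exp_percent" in budget:
            mean_uexp = round_half_away(float(budget["u_exp_percent"].mean()), 1)
            parts.append("")
            parts.append(f"Mean expanded uncertainty: {mean_uexp}%")

    def r_survey(s):
        rows = [dict(commodity=c, **v) for c, v in s["per_commodity"].items()]
        parts.append(_table(pd.DataFrame(rows)))
        parts.append("")
        parts.append(
            f"Positive samples: {s['n_positive']} of {s['n_samples']} "
            f"({s['positive_pct']}%)."
        )
        if s.get("max_concentration"):
            m = s["max_concentration"]
            parts.append(
                f"Highest residue: {m['analyte']} in {m['commodity']} at "
                f"{m['conc_ugkg']} ug/kg."
            )
        else:
            parts.append("No quantifiable residues found (zero positives).")

    section("Screening (main effects)", "screening", r_screening)
    section("Desirability optimum", "optimum", r_optimum)
    section("Calibration and matrix effects", "matrix_effects", r_me)
    section("Recovery and precision", "recovery", r_recovery)
    section("Measurement-uncertainty budget", "budget", r_budget)
    section("Monitoring survey", "survey", r_survey)
    return "\n".join(parts)
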