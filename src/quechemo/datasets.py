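"""Reference validation tables for the five-pesticide QuEChERS LC-MS/MS method.

Small CSV tables shipped with the package: calibration slopes per analyte x
matrix x dilution (solvent = methanol), spiked-recovery summaries at three
levels, the per-analyte uncertainty components, and the detections from an
85-sample market monitoring survey.  They are the published reference inputs
for the validation and uncertainty stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validation import CalibrationCurve

__all__ = [
    "load_calibration_slopes",
    "load_recovery_table",
    "load_uncertainty_components",
    "load_survey_records",
    "reference_curve",
    "SURVEY_COMMODITY_COUNTS",
    "LOQS",
]

#: Sample counts of the monitoring survey (85 samples total).
SURVEY_COMMODITY_COUNTS = {
    "citrus": 20, "apple": 10, "mango": 10, "lychee": 20,
    "tomato": 5, "cucumber": 5, "green pepper": 10, "eggplant": 5,
}

#: Validated limits of quantification, ug/kg.
LOQS = {"2,4-D": 1.0, "carbendazim": 1.0, "thiabendazole": 1.0,
        "iprodione": 1.5, "prochloraz": 1.0}


def _load(name: str) -> pd.DataFrame:
    with resources.files("quechemo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_calibration_slopes() -> pd.DataFrame:
    """Calibration line parameters (slope, intercept, R^2) and the reported
    integer matrix effect per analyte x matrix x dilution."""
    df = _load("calibration_slopes.csv")
    df["me_printed"] = pd.to_numeric(df["me_printed"], errors="coerce")
    return df


def load_recovery_table() -> pd.DataFrame:
    """Mean recovery and intra/inter-day RSD per analyte x matrix x level."""
    return _load("recovery_table.csv")


def load_uncertainty_components() -> pd.DataFrame:
    """Reported relative uncertainty components u1-u4 per analyte, plus the
    reported combined (uc_printed) and expanded (uexp_printed, %) values."""
    return _load("uncertainty_components.csv")


def load_survey_records() -> pd.DataFrame:
    """Detections from the 85-sample monitoring survey (one row per detected
    analyte; samples without a row were blank / below LOD)."""
    return _load("survey_records.csv")


def reference_curve(analyte: str, matrix: str, dilution: str = "ND") -> CalibrationCurve:
    """Build a :class:`CalibrationCurve` from the reference slope table."""
    df = load_calibration_slopes()
    row = df[(df["analyte"] == analyte) & (df["matrix"] == matrix)
             & (df["dilution"] == dilution)]
    if len(row) != 1:
        raise KeyError(f"no reference curve for {analyte}/{matrix}/{dilution}")
    r = row.iloc[0]
    return CalibrationCurve(
        slope=float(r["slope"]), intercept=float(r["intercept"]),
        r_squared=float(r["r_squared"]), analyte=analyte, matrix=matrix,
        dilution=dilution,
    )
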