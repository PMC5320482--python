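"""Synthetic laboratory data with the structure the pipeline assumes.

Generates every input the analysis consumes: DOE response tables from
latent quadratic recovery surfaces, matrix-distorted calibration tables
whose distortion shrinks on dilution, spiked-recovery replicates with
within/between-day variance components, and low-prevalence contamination
surveys with left-censoring at the LOQ.

The truth (surfaces, matrix-effect factors, variance components) is fixed
by :class:`TruthSpec`; the seed only drives noise.  A single global seed
expands to per-stage child seeds via ``child_seed`` (a CRC32 hash of the
stage label mixed into a ``numpy`` ``SeedSequence``), so each stage is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import DesignMatrix

__all__ = [
    "TruthSpec",
    "ANALYTES",
    "COMMODITIES",
    "child_seed",
    "make_default_truth",
    "simulate_doe",
    "simulate_calibration",
    "simulate_recovery",
    "simulate_survey",
]

ANALYTES = ("2,4-D", "carbendazim", "thiabendazole", "iprodione", "prochloraz")
COMMODITIES = ("citrus", "apple", "mango", "lychee", "tomato", "cucumber",
               "green pepper", "eggplant")

CAL_LEVELS = (0.1, 1.0, 5.0, 10.0, 50.0, 100.0, 200.0)  # ug/L


def child_seed(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    keys = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31)] + keys))


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for all simulated stages.

    ``surfaces`` maps analyte -> {term: coefficient} for the latent recovery
    surface in coded units (terms: 'b0', factor names, 'name^2', 'a:b');
    responses are clipped to [0, 110] %.  ``me_factor`` multiplies the true
    calibration slope per matrix; 10-fold dilution shrinks the deviation
    from 1 by ``dilution_shrink`` (0.6 = 60 % reduction).  Recovery
    replicates get a between-day and a within-day Gaussian component.
    """

    surfaces: dict[str, dict[str, float]]
    noise_sd: float = 1.5            # DOE response noise, recovery %
    me_factor: dict[str, float] = field(default_factory=dict)
    dilution_shrink: float = 0.6
    calibration_cv: float = 0.02     # proportional signal noise
    true_slope: dict[str, float] = field(default_factory=dict)
    recovery_mean: dict[str, float] = field(default_factory=dict)
    recovery_sd_within: float = 3.0  # %
    recovery_sd_between: float = 2.0  # %
    prevalence: dict[str, float] | float = 0.12
    survey_log_mu: float = np.log(4.0)   # log ug/kg
    survey_log_sigma: float = 0.8
    loq: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def me_factor_for(self, matrix: str, dilution: str) -> float:
        f = 1.0 if matrix == "methanol" else self.me_factor[matrix]
        if dilution == "D10":
            f = 1.0 + (1.0 - self.dilution_shrink) * (f - 1.0)
        return f

    def prevalence_for(self, commodity: str) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence[commodity]
        return float(self.prevalence)


def _default_surfaces() -> dict[str, dict[str, float]]:
    # Toluene and HCl: positive linear effect with concave curvature, so the
    # screening effect is positive but the optimum is interior.  GCB: strong
    # negative linear term (boundary optimum at 0 mg) for three analytes,
    # weakly positive for 2,4-D and thiabendazole.
    common = {"toluene": 4.5, "hcl": 6.0, "toluene^2": -6.0, "hcl^2": -5.0}
    gcb = {"2,4-D": 0.75, "carbendazim": -8.0, "thiabendazole": 0.75,
           "iprodione": -8.5, "prochloraz": -7.5}
    b0 = {"2,4-D": 88.0, "carbendazim": 86.0, "thiabendazole": 90.0,
          "iprodione": 84.0, "prochloraz": 89.0}
    return {
        a: {"b0": b0[a], "gcb": gcb[a], **common} for a in ANALYTES
    }


def make_default_truth(seed: int = 0) -> TruthSpec:
    """Default study conditions (see docs/methods.md for rationale)."""
    return TruthSpec(
        surfaces=_default_surfaces(),
        me_factor={
            "citrus": 1.50, "apple": 1.10, "mango": 1.30, "lychee": 0.55,
            "tomato": 0.85, "cucumber": 1.25, "green pepper": 0.75,
            "eggplant": 0.60,
        },
        true_slope={"2,4-D": 2000.0, "carbendazim": 176000.0,
                    "thiabendazole": 122000.0, "iprodione": 262.0,
                    "prochloraz": 14500.0},
        recovery_mean={a: 85.0 for a in ANALYTES},
        prevalence={"citrus": 0.30, "apple": 0.20, "mango": 0.0,
                    "lychee": 0.05, "tomato": 0.20, "cucumber": 0.0,
                    "green pepper": 0.0, "eggplant": 0.0},
        loq={"2,4-D": 1.0, "carbendazim": 1.0, "thiabendazole": 1.0,
             "iprodione": 1.5, "prochloraz": 1.0},
        seed=seed,
    )


def surface_value(coeffs: dict[str, float], names: list[str], X: np.ndarray) -> np.ndarray:
    """Evaluate a truth surface at coded points X (n x len(names))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.full(X.shape[0], coeffs.get("b0", 0.0))
    for j, nm in enumerate(names):
        y += coeffs.get(nm, 0.0) * X[:, j]
        y += coeffs.get(f"{nm}^2", 0.0) * X[:, j] ** 2
        for k in range(j + 1, len(names)):
            c = coeffs.get(f"{nm}:{names[k]}", coeffs.get(f"{names[k]}:{nm}", 0.0))
            y += c * X[:, j] * X[:, k]
    return y


def simulate_doe(design: DesignMatrix, truth: TruthSpec, seed: int | None = None) -> pd.DataFrame:
    """Recovery responses (run x analyte) from the latent surfaces + noise."""
    names = design.factor_names
    rng = child_seed(truth.seed if seed is None else seed, "doe", design.n_runs)
    out = {}
    for a in truth.surfaces:
        y = surface_value(truth.surfaces[a], names, design.coded)
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
        out[a] = np.clip(y, 0.0, 110.0)
    df = pd.DataFrame(out)
    df.insert(0, "run_id", np.arange(design.n_runs))
    return df


def simulate_calibration(
    truth: TruthSpec,
    analyte: str,
    matrix: str,
    dilution: str = "ND",
    seed: int | None = None,
    levels=CAL_LEVELS,
) -> pd.DataFrame:
    """Calibration table: signal = slope * ME_factor * conc * (1 + eps)."""
    slope = truth.true_slope[analyte] * truth.me_factor_for(matrix, dilution)
    rng = child_seed(truth.seed if seed is None else seed,
                     "calibration", analyte, matrix, dilution)
    conc = np.asarray(levels, dtype=float)
    eps = rng.normal(0.0, truth.calibration_cv, size=conc.size)
    return pd.DataFrame({
        "analyte": analyte, "matrix": matrix, "dilution": dilution,
        "level_ugL": conc, "signal": slope * conc * (1.0 + eps),
    })


def simulate_recovery(
    truth: TruthSpec,
    analyte: str,
    matrix: str,
    level: str = "LOQ",
    n_days: int = 3,
    n_reps: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spiked-recovery replicates: truth mean + day effect + replicate noise."""
    rng = child_seed(truth.seed if seed is None else seed,
                     "recovery", analyte, matrix, level)
    mean = truth.recovery_mean[analyte]
    day_eff = rng.normal(0.0, truth.recovery_sd_between, size=n_days)
    rows = []
    for d in range(n_days):
        reps = mean + day_eff[d] + rng.normal(0.0, truth.recovery_sd_within, size=n_reps)
        for r, v in enumerate(reps):
            rows.append((analyte, matrix, level, d + 1, r + 1, v))
    return pd.DataFrame(rows, columns=["analyte", "matrix", "level_label",
                                       "day", "rep", "recovery_pct"])


def simulate_survey(
    truth: TruthSpec,
    commodity_counts: dict[str, int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Monitoring survey: per sample, contamination with commodity-specific
    prevalence; concentrations log-normal; below-LOQ values censored (NaN)."""
    rng = child_seed(truth.seed if seed is None else seed, "survey")
    sample_ids, commodities, analytes, concs = [], [], [], []
    weights = np.array([0.15, 0.45, 0.15, 0.15, 0.10])  # carbendazim most frequent
    analyte_arr = np.array(ANALYTES)
    i = 0
    for com, n in commodity_counts.items():
        if n < 0:
            raise ValueError("commodity counts must be >= 0")
        p = truth.prevalence_for(com)
        hit = rng.random(n) < p
        picked = analyte_arr[rng.choice(len(analyte_arr), size=n, p=weights / weights.sum())]
        conc = np.exp(rng.normal(truth.survey_log_mu, truth.survey_log_sigma, size=n))
        for j in range(n):
            i += 1
            sample_ids.append(f"S{i:03d}")
            commodities.append(com)
            if hit[j]:
                a = picked[j]
                analytes.append(a)
                c = conc[j]
                concs.append(c if c >= truth.loq.get(a, 0.0) else np.nan)
            else:
                analytes.append("")
                concs.append(np.nan)
    return pd.DataFrame({"sample_id": sample_ids, "commodity": commodities,
                         "analyte": analytes, "conc_ugkg": concs})
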