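"""End-to-end chemometric optimization workflow on synthetic data.

Wires the stages together the way the lab study ran them: Plackett–Burman
screening of five extraction factors, central composite optimization of the
significant three (toluene %, HCl %, GCB mg), and Derringer desirability
optimization over the five analyte recovery surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import desirability as dlib
from . import rsm, screening
from .designs import DesignMatrix, Factor, generate_ccd, generate_plackett_burman
from .synthetic import TruthSpec, child_seed, make_default_truth, simulate_doe

__all__ = [
    "SCREENING_FACTORS",
    "OPTIMIZATION_FACTORS",
    "PipelineResult",
    "run_screening",
    "run_optimization",
    "run_pipeline",
]

#: The five screened extraction factors with their natural ranges.
SCREENING_FACTORS = [
    Factor("toluene", 0.0, 100.0, "X1"),   # % v/v of the extraction solvent
    Factor("hcl", 0.0, 0.5, "X2"),         # % v/v HCl in the extraction solution
    Factor("psa", 0.0, 50.0, "X3"),        # mg PSA sorbent
    Factor("c18", 0.0, 20.0, "X4"),        # mg C18 sorbent
    Factor("gcb", 0.0, 20.0, "X5"),        # mg GCB sorbent
]

#: The three factors carried into the response-surface optimization.
OPTIMIZATION_FACTORS = [f for f in SCREENING_FACTORS if f.name in ("toluene", "hcl", "gcb")]


@dataclass
class PipelineResult:
    screening_effects: dict[str, screening.EffectTable]
    significant_factors: list[str]
    models: dict[str, rsm.QuadraticModel]
    optimum: dlib.Optimum


def run_screening(
    truth: TruthSpec, seed: int, n_center: int = 3
) -> tuple[DesignMatrix, pd.DataFrame, dict[str, screening.EffectTable]]:
    """P-B screening of all five factors: simulate, estimate, test."""
    design = generate_plackett_burman(SCREENING_FACTORS, n_center=n_center)
    responses = simulate_doe(design, truth, seed=seed)
    tables = {}
    for analyte in truth.surfaces:
        y = responses[analyte].to_numpy()
        eff = screening.main_effects(design, y)
        s_pe, df_pe = screening.pure_error(y[design.is_center])
        tables[analyte] = screening.test_effects(eff, s_pe, df_pe)
    return design, responses, tables


def run_optimization(
    truth: TruthSpec, seed: int, n_center: int = 6
) -> tuple[DesignMatrix, pd.DataFrame, dict[str, rsm.QuadraticModel], dlib.Optimum]:
    """Rotatable CCD on the three significant factors + desirability optimum."""
    design = generate_ccd(OPTIMIZATION_FACTORS, n_center=n_center)
    responses = simulate_doe(design, truth, seed=seed)
    models = {}
    for analyte in truth.surfaces:
        model = rsm.fit_quadratic(design, responses[analyte].to_numpy())
        rsm.anova_lof(model, design, responses[analyte].to_numpy())
        models[analyte] = model
    optimum = dlib.optimize(models, specs="auto")
    nat = {}
    for j, fac in enumerate(design.factors):
        from .designs import to_natural

        nat[fac.name] = max(float(to_natural(optimum.coded[j], fac)), 0.0) \
            if fac.low_natural >= 0 else float(to_natural(optimum.coded[j], fac))
    optimum.natural = nat
    return design, responses, models, optimum


def run_pipeline(seed: int = 0, truth: TruthSpec | None = None) -> PipelineResult:
    """Screening -> optimization -> desirability, all from one seed."""
    truth = truth if truth is not None else make_default_truth(seed)
    scr_seed = int(child_seed(seed, "pipeline", "screening").integers(2**31))
    opt_seed = int(child_seed(seed, "pipeline", "optimization").integers(2**31))
    _, _, tables = run_screening(truth, seed=scr_seed)
    # A factor goes forward if it is significant for any analyte.
    sig: list[str] = []
    for name in [f.name for f in SCREENING_FACTORS]:
        if any(t.table.loc[name, "significant"] is True
               or t.table.loc[name, "significant"] == True  # noqa: E712 (pandas BooleanDtype)
               for t in tables.values()):
            sig.append(name)
    _, _, models, optimum = run_optimization(truth, seed=opt_seed)
    return PipelineResult(
        screening_effects=tables,
        significant_factors=sig,
        models=models,
        optimum=optimum,
    )
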