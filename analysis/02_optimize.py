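"""Stage 2 — Central composite optimization and desirability maximization.

Builds the rotatable CCD for the three significant factors (toluene %,
HCl %, GCB mg), simulates responses, fits the 10-term quadratic model per
pesticide with the lack-of-fit ANOVA, and maximizes Derringer's overall
desirability over the coded cube.

Run:  python analysis/02_optimize.py [seed]
"""

import json
import sys
from pathlib import Path

import pandas as pd

from quechemo import desirability, pipeline, rsm
from quechemo.designs import write_design_csv
from quechemo.synthetic import make_default_truth

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    truth = make_default_truth(seed)
    design, responses, models, optimum = pipeline.run_optimization(truth, seed=seed)
    write_design_csv(design, OUT / "design_ccd.csv")
    responses.to_csv(OUT / "responses_ccd.csv", index=False)

    coef_rows, anova_rows = [], []
    for analyte, m in models.items():
        for term in m.terms:
            coef_rows.append(dict(analyte=analyte, term=term,
                                  coefficient=m.coef[term], se=m.se[term],
                                  t=m.t[term], p=m.p[term]))
        anova_rows.append(dict(analyte=analyte, r_squared=m.r_squared,
                               p_lof=m.anova.get("p_lof"),
                               p_model=m.anova.get("p_model")))
    pd.DataFrame(coef_rows).to_csv(OUT / "rsm_coefficients.csv", index=False)
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(OUT / "rsm_anova.csv", index=False)

    specs = {a: desirability.auto_range_spec(m) for a, m in models.items()}
    profiles = desirability.desirability_profiles(models, specs, optimum)
    profiles.to_csv(OUT / "desirability_profiles.csv", index=False)
    # numeric surface grids (toluene x hcl at the optimum's GCB)
    grids = []
    for analyte, m in models.items():
        g = rsm.surface_grid_frame(m, (0, 1), fixed_values={2: optimum.coded[2]},
                                   grid_n=21)
        g.insert(0, "analyte", analyte)
        grids.append(g)
    pd.concat(grids).to_csv(OUT / "surface_grids.csv", index=False)

    payload = dict(coded={f.name: float(v) for f, v in
                          zip(design.factors, optimum.coded)},
                   natural=optimum.natural, predictions=optimum.predictions,
                   d=optimum.d, D=optimum.D)
    (OUT / "optimum.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    print("per-analyte fit quality:")
    print(anova.round(4).to_string(index=False))
    print(f"optimum (coded): {payload['coded']}")
    print(f"optimum (natural): { {k: round(v, 3) for k, v in optimum.natural.items()} }")
    print(f"overall desirability D = {optimum.D:.3f}")
    if payload["coded"]["gcb"] <= -0.95:
        print("the GCB coordinate sits on the low boundary: 0 mg GCB is optimal")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
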