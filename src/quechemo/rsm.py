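"""Second-order response-surface model fitting with lack-of-fit ANOVA.

The full quadratic basis in coded units — intercept, f linear terms, f pure
quadratics and f(f-1)/2 two-way interactions (10 terms for f = 3) — is fit
per analyte by ordinary least squares.  The residual sum of squares is
partitioned into lack-of-fit and pure error over the replicated (center)
points; a non-significant lack-of-fit F-test supports the quadratic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "QuadraticModel",
    "SingularDesignError",
    "quadratic_terms",
    "quadratic_basis",
    "fit_quadratic",
    "anova_lof",
    "predict",
    "surface_grid",
]


class SingularDesignError(ValueError):
    pass


def quadratic_terms(names: list[str]) -> list[str]:
    """Term labels in canonical order: 1, x_i, x_i^2, x_i:x_j (i<j)."""
    f = len(names)
    terms = ["intercept"] + list(names)
    terms += [f"{n}^2" for n in names]
    terms += [f"{names[i]}:{names[j]}" for i in range(f) for j in range(i + 1, f)]
    return terms


def quadratic_basis(X: np.ndarray) -> np.ndarray:
    """Model matrix of the full second-order basis for coded points X (n x f)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, f = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(f)]
    cols += [X[:, i] ** 2 for i in range(f)]
    cols += [X[:, i] * X[:, j] for i in range(f) for j in range(i + 1, f)]
    return np.column_stack(cols)


def _independent_columns(B: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Greedy scan for a maximal independent column subset (small matrices)."""
    keep: list[int] = []
    for j in range(B.shape[1]):
        trial = B[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(1.0, np.abs(B).max())) == len(keep) + 1:
            keep.append(j)
    return keep


@dataclass
class QuadraticModel:
    """Fitted second-order surface for one response.

    Coefficients are in coded units.  ``anova`` is filled by
    :func:`anova_lof` with the SS/df/F/p decomposition
    (SS_residual = SS_lof + SS_pe).
    """

    factor_names: tuple[str, ...]
    terms: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    r_squared: float
    ss_model: float
    ss_residual: float
    df_residual: int
    fitted_terms: tuple[str, ...] = ()
    anova: dict = field(default_factory=dict)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)


def fit_quadratic(
    design: DesignMatrix, responses, include_terms: list[str] | None = None
) -> QuadraticModel:
    """OLS fit of the full quadratic basis (10 terms for f=3) in coded units.

    ``include_terms`` prunes the basis to a subset of term labels (the
    intercept is always kept); the default is the full model.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError("responses length does not match design rows")
    full_terms = quadratic_terms(design.factor_names)
    B_full = quadratic_basis(design.coded)
    if include_terms is None:
        terms, B = full_terms, B_full
    else:
        unknown = set(include_terms) - set(full_terms)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        keep = [j for j, t in enumerate(full_terms)
                if t == "intercept" or t in include_terms]
        terms = [full_terms[j] for j in keep]
        B = B_full[:, keep]
    n_distinct = len({tuple(row) for row in design.coded})
    if n_distinct < len(terms):
        raise SingularDesignError(
            f"{n_distinct} distinct design points cannot support {len(terms)} terms"
        )
    rank = np.linalg.matrix_rank(B)
    if rank < B.shape[1]:
        indep = _independent_columns(B)
        collinear = [terms[j] for j in range(B.shape[1]) if j not in indep]
        raise SingularDesignError(f"design basis is rank-deficient; collinear terms: {collinear}")

    if np.ptp(y) == 0.0:
        # Zero-variance response: intercept-only fit, R^2 defined as 0.
        warnings.warn("constant response: all non-intercept coefficients set to 0, R^2 = 0",
                      stacklevel=2)
        coef = pd.Series(0.0, index=full_terms)
        coef["intercept"] = y.mean()
        nan = pd.Series(np.nan, index=full_terms)
        return QuadraticModel(
            factor_names=tuple(design.factor_names), terms=tuple(full_terms),
            coef=coef, se=nan, t=nan, p=nan, r_squared=0.0,
            ss_model=0.0, ss_residual=0.0, df_residual=len(y) - len(terms),
            fitted_terms=tuple(terms),
        )

    res = sm.OLS(y, B).fit()
    ss_res = float(res.ssr)
    ss_model = float(res.ess)
    # Coefficients live on the full basis so prediction is uniform; pruned
    # terms get coefficient 0 and NaN inference.
    coef = pd.Series(res.params, index=terms).reindex(full_terms, fill_value=0.0)
    return QuadraticModel(
        factor_names=tuple(design.factor_names),
        terms=tuple(full_terms),
        coef=coef,
        se=pd.Series(res.bse, index=terms).reindex(full_terms),
        t=pd.Series(res.tvalues, index=terms).reindex(full_terms),
        p=pd.Series(res.pvalues, index=terms).reindex(full_terms),
        r_squared=float(ss_model / (ss_model + ss_res)) if ss_model + ss_res > 0 else 0.0,
        ss_model=ss_model,
        ss_residual=ss_res,
        df_residual=int(res.df_resid),
        fitted_terms=tuple(terms),
    )


def anova_lof(model: QuadraticModel, design: DesignMatrix, responses) -> dict:
    """ANOVA with the residual split into lack-of-fit and pure error.

    Pure error pools the within-group variation over all exactly replicated
    coded points (center rows, for a CCD); F_lof = MS_lof / MS_pe.  The
    result is stored on ``model.anova`` and returned.
    """
    y = np.asarray(responses, dtype=float)
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(design.coded):
        groups.setdefault(tuple(row), []).append(i)
    ss_pe = 0.0
    df_pe = 0
    for idx in groups.values():
        if len(idx) > 1:
            g = y[idx]
            ss_pe += float(((g - g.mean()) ** 2).sum())
            df_pe += len(idx) - 1
    anova: dict = {
        "ss_model": model.ss_model,
        "df_model": len(model.fitted_terms or model.terms) - 1,
        "ss_residual": model.ss_residual,
        "df_residual": model.df_residual,
    }
    ms_model = model.ss_model / max(anova["df_model"], 1)
    if model.df_residual > 0 and model.ss_residual > 0:
        f_model = ms_model / (model.ss_residual / model.df_residual)
        anova["f_model"] = f_model
        anova["p_model"] = float(
            stats.f.sf(f_model, anova["df_model"], model.df_residual)
        )
    if df_pe == 0:
        anova["lof_available"] = False
        warnings.warn("no replicated design points: lack-of-fit test unavailable",
                      stacklevel=2)
    else:
        df_lof = model.df_residual - df_pe
        ss_lof = max(model.ss_residual - ss_pe, 0.0)
        anova.update(ss_pe=ss_pe, df_pe=df_pe, ss_lof=ss_lof, df_lof=df_lof,
                     lof_available=df_lof >= 1)
        if df_lof >= 1 and ss_pe > 0 and df_pe >= 1:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            anova["f_lof"] = f_lof
            anova["p_lof"] = float(stats.f.sf(f_lof, df_lof, df_pe))
    model.anova = anova
    return anova


def predict(model: QuadraticModel, coded_point) -> np.ndarray | float:
    """Evaluate the fitted polynomial at one or many coded points."""
    pt = np.asarray(coded_point, dtype=float)
    single = pt.ndim == 1
    pts = np.atleast_2d(pt)
    if pts.shape[1] != model.n_factors:
        raise ValueError(
            f"expected {model.n_factors} coordinates, got {pts.shape[1]}"
        )
    out = quadratic_basis(pts) @ model.coef.to_numpy()
    return float(out[0]) if single else out


def surface_grid(
    model: QuadraticModel,
    axis_pair: tuple[int, int],
    fixed_values: dict[int, float] | None = None,
    grid_n: int = 21,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prediction grid over two factors with the rest held fixed.

    Returns ``(g1, g2, Z)`` with ``Z[i, j]`` the prediction at
    ``axis1 = g1[i], axis2 = g2[j]`` — the numeric content of a 3-D response
    surface plot.
    """
    a1, a2 = axis_pair
    fixed_values = fixed_values or {}
    g = np.linspace(bounds[0], bounds[1], grid_n)
    pts = np.zeros((grid_n * grid_n, model.n_factors))
    for k, v in fixed_values.items():
        pts[:, k] = v
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    pts[:, a1] = G1.ravel()
    pts[:, a2] = G2.ravel()
    Z = predict(model, pts).reshape(grid_n, grid_n)
    return g, g, Z


def surface_grid_frame(model, axis_pair, **kwargs) -> pd.DataFrame:
    """Long-format export of :func:`surface_grid` (x1, x2, prediction)."""
    g1, g2, Z = surface_grid(model, axis_pair, **kwargs)
    n1 = model.factor_names[axis_pair[0]]
    n2 = model.factor_names[axis_pair[1]]
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    return pd.DataFrame({n1: G1.ravel(), n2: G2.ravel(), "prediction": Z.ravel()})
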