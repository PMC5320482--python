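"""Two-level screening and second-order response-surface designs.

Implements the 12-run Plackett–Burman design (with replicated center points
for a pure-error estimate) and the central composite design (CCD) used to
optimize the significant factors of a QuEChERS extraction.  All designs are
held in coded units: the center of a factor's natural range maps to 0 and
its half-range to 1, so a two-level design lives on {-1, +1} and CCD star
points sit at +/- alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "InvalidDesignError",
    "PB12_GENERATOR",
    "generate_plackett_burman",
    "generate_ccd",
    "to_coded",
    "to_natural",
    "randomize_run_order",
    "write_design_csv",
    "read_design_csv",
]

#: First row of the standard 12-run Plackett-Burman cyclic construction.
PB12_GENERATOR = np.array([+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1], dtype=float)


class InvalidDesignError(ValueError):
    """Raised when a requested design cannot be constructed."""


@dataclass(frozen=True)
class Factor:
    """A continuous experimental factor with a natural low/high range.

    ``low_natural``/``high_natural`` are the -1/+1 levels in natural units
    (e.g. toluene 0-100 % v/v, GCB 0-20 mg); ``symbol`` is the short design
    label (X1...X5).
    """

    name: str
    low_natural: float
    high_natural: float
    symbol: str = ""

    def __post_init__(self) -> None:
        if not self.high_natural > self.low_natural:
            raise InvalidDesignError(
                f"factor {self.name!r}: low_natural must be < high_natural "
                f"(got {self.low_natural} >= {self.high_natural})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low_natural + self.high_natural)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high_natural - self.low_natural)


def to_coded(value: float, factor: Factor) -> float:
    """Natural units -> coded units (center 0, half-range 1)."""
    return (value - factor.midpoint) / factor.half_range


def to_natural(coded: float, factor: Factor) -> float:
    """Coded units -> natural units (inverse of :func:`to_coded`)."""
    return factor.midpoint + np.asarray(coded, dtype=float) * factor.half_range


@dataclass(frozen=True)
class DesignMatrix:
    """A coded experimental design: runs x factors plus run metadata.

    ``point_type`` labels each run as ``factorial``, ``star`` or ``center``;
    ``run_order`` is the (possibly randomized) execution order of the rows.
    """

    factors: tuple[Factor, ...]
    coded: np.ndarray
    point_type: tuple[str, ...]
    run_order: tuple[int, ...]
    seed: int | None = None
    #: extra metadata (e.g. CCD alpha, clamped natural cells)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float)
        object.__setattr__(self, "coded", coded)
        n_runs, n_fac = coded.shape
        if n_fac != len(self.factors):
            raise InvalidDesignError("coded matrix width does not match factor count")
        if len(self.point_type) != n_runs or len(self.run_order) != n_runs:
            raise InvalidDesignError("run metadata length does not match run count")
        if sorted(self.run_order) != list(range(n_runs)):
            raise InvalidDesignError("run_order must be a permutation of 0..n-1")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded.shape[1]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def is_center(self) -> np.ndarray:
        return np.array([pt == "center" for pt in self.point_type])

    def natural(self, clamp_nonnegative: bool = True) -> np.ndarray:
        """Design in natural units.

        Star points of a rotatable CCD on a factor whose natural low is a
        physical zero (e.g. 0 mg sorbent) extrapolate below zero; such cells
        are clamped to 0 with a warning and recorded in ``meta['clamped']``.
        """
        nat = np.empty_like(self.coded)
        clamped: list[tuple[int, str]] = []
        for j, fac in enumerate(self.factors):
            nat[:, j] = to_natural(self.coded[:, j], fac)
            if clamp_nonnegative and fac.low_natural >= 0.0:
                below = nat[:, j] < 0.0
                if below.any():
                    clamped.extend((int(i), fac.name) for i in np.nonzero(below)[0])
                    nat[below, j] = 0.0
        if clamped:
            self.meta.setdefault("clamped", clamped)
            warnings.warn(
                f"{len(clamped)} natural design cell(s) fell below physical zero "
                "and were clamped to 0",
                stacklevel=2,
            )
        return nat


def generate_plackett_burman(factors: list[Factor], n_center: int = 3) -> DesignMatrix:
    """12-run Plackett–Burman screening design plus ``n_center`` center points.

    The 12 two-level rows come from the standard cyclic construction: the
    generator row, its 10 cyclic right-shifts, and a final all-minus row.
    Only the first ``len(factors)`` columns are kept; every kept column is
    balanced (6 highs / 6 lows) and any two columns are orthogonal.
    """
    k = len(factors)
    if not 2 <= k <= 11:
        raise InvalidDesignError(f"Plackett-Burman supports 2-11 factors, got {k}")
    if n_center < 0:
        raise InvalidDesignError("n_center must be >= 0")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise InvalidDesignError("factor names must be unique within a design")

    rows = [np.roll(PB12_GENERATOR, shift) for shift in range(11)]
    rows.append(-np.ones(11))
    full = np.vstack(rows)  # 12 x 11
    coded = full[:, :k]
    if n_center:
        coded = np.vstack([coded, np.zeros((n_center, k))])
    point_type = ("factorial",) * 12 + ("center",) * n_center
    return DesignMatrix(
        factors=tuple(factors),
        coded=coded,
        point_type=point_type,
        run_order=tuple(range(12 + n_center)),
    )


def generate_ccd(
    factors: list[Factor],
    alpha_mode: str = "rotatable",
    n_center: int = 6,
    alpha: float | None = None,
) -> DesignMatrix:
    """Central composite design: 2^f factorial + 2f star + n_center center runs.

    ``alpha_mode='rotatable'`` places the star points at alpha = (2^f)^(1/4),
    which makes the prediction variance of the fitted quadratic model depend
    only on the distance from the design center; ``'face_centered'`` uses
    alpha = 1; ``'custom'`` requires an explicit ``alpha``.
    """
    f = len(factors)
    if not 2 <= f <= 6:
        raise InvalidDesignError(f"CCD supports 2-6 factors, got {f}")
    if n_center < 1:
        raise InvalidDesignError(
            "CCD requires n_center >= 1 (pure error needs center replication)"
        )
    names = [fac.name for fac in factors]
    if len(set(names)) != len(names):
        raise InvalidDesignError("factor names must be unique within a design")

    if alpha_mode == "rotatable":
        a = (2.0**f) ** 0.25
    elif alpha_mode == "face_centered":
        a = 1.0
    elif alpha_mode == "custom":
        if alpha is None or alpha <= 0:
            raise InvalidDesignError("alpha_mode='custom' requires alpha > 0")
        a = float(alpha)
    else:
        raise InvalidDesignError(f"unknown alpha_mode {alpha_mode!r}")

    factorial = np.array(list(itertools.product((-1.0, 1.0), repeat=f)))
    star = np.zeros((2 * f, f))
    for j in range(f):
        star[2 * j, j] = -a
        star[2 * j + 1, j] = +a
    center = np.zeros((n_center, f))
    coded = np.vstack([factorial, star, center])
    point_type = (
        ("factorial",) * len(factorial) + ("star",) * len(star) + ("center",) * n_center
    )
    return DesignMatrix(
        factors=tuple(factors),
        coded=coded,
        point_type=point_type,
        run_order=tuple(range(len(coded))),
        meta={"alpha": a, "alpha_mode": alpha_mode},
    )


def randomize_run_order(design: DesignMatrix, seed: int) -> DesignMatrix:
    """Assign a seeded random execution order; design content is untouched."""
    rng = np.random.default_rng(seed)
    perm = tuple(int(i) for i in rng.permutation(design.n_runs))
    return replace(design, run_order=perm, seed=seed)


# ---------------------------------------------------------------------------
# CSV dialect: run_id, point_type, <name>_coded..., <name>_natural..., run_order


def design_to_frame(design: DesignMatrix) -> pd.DataFrame:
    nat = design.natural()
    data: dict[str, object] = {
        "run_id": np.arange(design.n_runs),
        "point_type": list(design.point_type),
    }
    for j, fac in enumerate(design.factors):
        data[f"{fac.name}_coded"] = design.coded[:, j]
    for j, fac in enumerate(design.factors):
        data[f"{fac.name}_natural"] = nat[:, j]
    data["run_order"] = list(design.run_order)
    return pd.DataFrame(data)


def write_design_csv(design: DesignMatrix, path) -> None:
    design_to_frame(design).to_csv(path, index=False)


def read_design_csv(path, factors: list[Factor]) -> DesignMatrix:
    df = pd.read_csv(path)
    coded = np.column_stack([df[f"{fac.name}_coded"].to_numpy() for fac in factors])
    return DesignMatrix(
        factors=tuple(factors),
        coded=coded,
        point_type=tuple(df["point_type"]),
        run_order=tuple(int(i) for i in df["run_order"]),
    )
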