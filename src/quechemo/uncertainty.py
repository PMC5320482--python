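"""Bottom-up (EURACHEM-style) measurement-uncertainty budget.

Four relative standard-uncertainty components — standards/stock preparation
(u1), calibration (u2), precision (u3) and accuracy/recovery (u4) — are
combined root-sum-square into u_c and expanded with coverage factor k = 2
(~95 % confidence) to U_exp (%) = 100 * k * u_c.  All components are stored
as dimensionless relative fractions; percent appears only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .validation import CalibrationCurve, round_half_away

__all__ = [
    "StandardsPrepSpec",
    "UncertaintyBudget",
    "u_standards",
    "u_calibration",
    "u_precision",
    "u_recovery",
    "combine",
    "expand",
    "build_budget",
]

_DIVISORS = {"rectangular": math.sqrt(3.0), "triangular": math.sqrt(6.0), "normal": 1.0}


@dataclass(frozen=True)
class StandardsPrepSpec:
    """Tolerance budget for preparing standards and stock solutions.

    ``purity``/``mass`` are (nominal, tolerance) pairs; ``volumes`` is a list
    of (nominal_mL, tolerance_mL, temperature_sd_mL) volumetric steps.  The
    temperature term is already a standard uncertainty; stated tolerances
    are converted per ``distribution`` (rectangular: / sqrt(3)).
    """

    purity: tuple[float, float] = (1.0, 0.0)
    mass: tuple[float, float] = (1.0, 0.0)
    volumes: tuple[tuple[float, float, float], ...] = ()
    distribution: str = "rectangular"


def u_standards(spec: StandardsPrepSpec) -> float:
    """Propagation-of-errors u1: RSS of the relative standard uncertainties
    of purity, weighing and each volumetric step."""
    div = _DIVISORS[spec.distribution]
    total = 0.0
    for nominal, tol in (spec.purity, spec.mass):
        if nominal == 0:
            raise ValueError("zero nominal quantity in standards spec")
        total += (tol / div / nominal) ** 2
    for nominal, tol, temp_sd in spec.volumes:
        if nominal == 0:
            raise ValueError("zero nominal volume in standards spec")
        total += (tol / div / nominal) ** 2 + (temp_sd / nominal) ** 2
    return math.sqrt(total)


def u_calibration(curve: CalibrationCurve, m: int, x0: float) -> float:
    """Relative uncertainty of a concentration read off the calibration line.

    s_x0 = (s_y/|slope|) * sqrt(1/m + 1/n + (x0 - x_bar)^2 / Sxx) for m
    replicate signal measurements; returns s_x0 / x0.
    """
    if x0 <= 0:
        raise ValueError("target concentration x0 must be > 0")
    if m < 1:
        raise ValueError("replicate count m must be >= 1")
    if not curve.usable:
        raise ValueError("calibration slope is zero")
    if math.isnan(curve.residual_sd):
        raise ValueError("curve has no residual SD (fit it from raw levels/signals)")
    s_x0 = (curve.residual_sd / abs(curve.slope)) * math.sqrt(
        1.0 / m + 1.0 / curve.n + (x0 - curve.x_mean) ** 2 / curve.sxx
    )
    return s_x0 / x0


def u_precision(rsd_percent: float, n_assay: int | None = None) -> float:
    """Precision component from a repeatability / intermediate-precision RSD.

    Per-determination by default (rsd/100); pass ``n_assay`` when the
    reported result is a mean of n determinations (divides by sqrt(n)).
    """
    if rsd_percent < 0:
        raise ValueError("RSD must be >= 0")
    u = rsd_percent / 100.0
    if n_assay is not None:
        u /= math.sqrt(n_assay)
    return u


def u_recovery(mean_recovery: float, sd_recovery: float, n: int) -> float:
    """Relative uncertainty of the mean recovery: (s_R/sqrt(n)) / R_bar."""
    if mean_recovery <= 0:
        raise ValueError("mean recovery must be > 0")
    if n < 2:
        raise ValueError("recovery component needs n >= 2 assays")
    return (sd_recovery / math.sqrt(n)) / mean_recovery


def combine(u1: float, u2: float, u3: float, u4: float) -> float:
    """u_c = sqrt(u1^2 + u2^2 + u3^2 + u4^2)."""
    comps = (u1, u2, u3, u4)
    if any(u < 0 for u in comps):
        raise ValueError("uncertainty components must be >= 0")
    return math.sqrt(sum(u * u for u in comps))


def expand(u_c: float, k: float = 2.0) -> float:
    """Expanded uncertainty in percent: U_exp = 100 * k * u_c."""
    if u_c < 0:
        raise ValueError("combined uncertainty must be >= 0")
    return 100.0 * k * u_c


@dataclass(frozen=True)
class UncertaintyBudget:
    """The four components plus their combination for one analyte."""

    analyte: str
    u1: float
    u2: float
    u3: float
    u4: float
    k: float = 2.0
    u_c: float = field(init=False)
    u_exp_percent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "u_c", combine(self.u1, self.u2, self.u3, self.u4))
        object.__setattr__(self, "u_exp_percent", expand(self.u_c, self.k))

    @property
    def u_c_display(self) -> float:
        """u_c rounded to 4 decimals (half away from zero)."""
        return round_half_away(self.u_c, 4)

    @property
    def u_exp_display(self) -> float:
        """U_exp (%) rounded to 1 decimal (half away from zero)."""
        return round_half_away(self.u_exp_percent, 1)


def build_budget(analyte: str, u1: float, u2: float, u3: float, u4: float,
                 k: float = 2.0) -> UncertaintyBudget:
    return UncertaintyBudget(analyte=analyte, u1=u1, u2=u2, u3=u3, u4=u4, k=k)
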