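"""Post-deployment survival as a function of in-facility growth time.

A cultivated unit (a coral fragment settled on a deployment device) is
held in a land-based facility for a growth time ``t`` (years) before being
deployed to a reef.  The fraction of deployed units still alive one year
after deployment, ``P(t)``, is modelled by one of four parametric
functional forms, each truncated to the band ``[0, pmax]``:

``asymptotic``
    ``P(t) = pmax - 1 / (c (t - t0) + 1/pmax)`` — increasing and concave,
    approaching the ceiling ``pmax``; the base-case form.
``linear``
    ``P(t) = c (t - t0)`` — a straight ramp with gradient ``c`` and
    x-intercept ``t0``.
``logistic``
    ``P(t) = pmax / (1 + exp(-c (t - t0)))`` — sigmoid with inflection at
    ``t0``.
``pseudo_gamma``
    ``P(t) = c (t - t0) exp(-c (t - t0))`` — rises to a peak at
    ``t0 + 1/c`` then decays, capturing units that acclimate to the
    facility and fare worse in the wild when held too long.

Because demand is stated in *surviving* units, producing ``X`` units at
growth time ``t`` yields ``P(t) * X`` survivors; meeting a demand ``D``
therefore requires producing ``D / P(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "SURVIVAL_FORMS",
    "SurvivalSpec",
    "GridPoint",
    "evaluate_survival",
    "survival_grid",
    "required_production",
]

SURVIVAL_FORMS = ("asymptotic", "linear", "logistic", "pseudo_gamma")


class SurvivalConfigError(ValueError):
    """Raised for an invalid survival specification."""


class UndefinedProductionError(ValueError):
    """Raised when production is requested at non-positive survival."""


@dataclass(frozen=True)
class SurvivalSpec:
    """Parametric survival curve specification.

    Parameters
    ----------
    form:
        One of :data:`SURVIVAL_FORMS`.
    c:
        Scaling factor (gradient-like; per-year units for the linear and
        logistic forms, dimensionless scale otherwise). Must be positive.
    t0:
        Horizontal shift in years (the x-intercept for the asymptotic,
        linear and pseudo-gamma forms; the inflection point for the
        logistic form).
    pmax:
        Maximum proportional survival, the ceiling of the truncation band.
    pmin:
        Survival floor applied as a lower clamp after truncation.
        Default 0, a no-op.
    pmin_allow:
        Allowable-minimum cutoff: growth times whose survival does not
        exceed this value are excluded from optimization, since they imply
        enormous production quantities.
    """

    form: str = "asymptotic"
    c: float = 25.0
    t0: float = 0.0
    pmax: float = 0.1
    pmin: float = 0.0
    pmin_allow: float = 1e-4

    def __post_init__(self) -> None:
        if self.form not in SURVIVAL_FORMS:
            raise SurvivalConfigError(
                f"unknown survival form {self.form!r}; expected one of {SURVIVAL_FORMS}"
            )
        if not (0.0 < self.pmax <= 1.0):
            raise SurvivalConfigError(f"pmax must be in (0, 1], got {self.pmax}")
        if not (0.0 <= self.pmin < self.pmax):
            raise SurvivalConfigError(
                f"pmin must satisfy 0 <= pmin < pmax, got pmin={self.pmin}, pmax={self.pmax}"
            )
        if self.pmin_allow < 0.0:
            raise SurvivalConfigError(f"pmin_allow must be >= 0, got {self.pmin_allow}")
        if not self.c > 0.0:
            raise SurvivalConfigError(f"c must be positive, got {self.c}")

    def __call__(self, t: float) -> float:
        return evaluate_survival(self, t)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "c": self.c,
            "t0": self.t0,
            "pmax": self.pmax,
            "pmin": self.pmin,
            "pmin_allow": self.pmin_allow,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalSpec":
        kw: dict = {k: float(d[k]) for k in
                    ("c", "t0", "pmax", "pmin", "pmin_allow") if k in d}
        if "form" in d:
            kw["form"] = str(d["form"])
        return cls(**kw)


def _raw_survival(spec: SurvivalSpec, t: float) -> float:
    x = spec.c * (t - spec.t0)
    if spec.form == "asymptotic":
        denom = x + 1.0 / spec.pmax
        if denom <= 0.0:
            # below the pole the curve is not meaningful; truncates to 0
            return 0.0
        return spec.pmax - 1.0 / denom
    if spec.form == "linear":
        return x
    if spec.form == "logistic":
        return spec.pmax / (1.0 + math.exp(-x))
    if spec.form == "pseudo_gamma":
        return x * math.exp(-x)
    raise SurvivalConfigError(f"unknown survival form {spec.form!r}")


def evaluate_survival(spec: SurvivalSpec, t: float) -> float:
    """Truncated proportional survival at growth time ``t`` (years).

    The raw functional form is clamped into ``[0, pmax]`` (values at or
    below zero map to 0; values above ``pmax`` map to ``pmax``), then the
    optional floor ``pmin`` is applied as a lower clamp.
    """
    if not math.isfinite(t):
        raise ValueError(f"growth time must be finite, got {t}")
    p = _raw_survival(spec, t)
    if p <= 0.0:
        p = 0.0
    elif p > spec.pmax:
        p = spec.pmax
    if p < spec.pmin:
        p = spec.pmin
    return p


@dataclass(frozen=True)
class GridPoint:
    """One growth-time grid entry: ``(t, P(t), included?)``."""

    t: float
    survival: float
    included: bool = field(default=True)


def survival_grid(
    spec: SurvivalSpec, t_min: float, t_max: float, dt: float
) -> list[GridPoint]:
    """Evaluate survival on the arithmetic grid ``t_min, t_min+dt, ... <= t_max``.

    Entries whose survival is at or below ``spec.pmin_allow`` are flagged
    ``included=False``; the optimizer skips them but they are reported so a
    caller can see which growth times were excluded and why.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_min > t_max:
        raise ValueError(f"empty grid: t_min={t_min} > t_max={t_max}")
    points: list[GridPoint] = []
    k = 0
    # half-open accumulation with tolerance so t_max lands on the grid
    # when it is an exact multiple of dt away from t_min
    while True:
        t = t_min + k * dt
        if t > t_max + 1e-12:
            break
        t = min(t, t_max)
        p = evaluate_survival(spec, t)
        points.append(GridPoint(t=t, survival=p, included=p > spec.pmin_allow))
        k += 1
    if not points:
        raise ValueError("empty growth-time grid")
    return points


def included_times(grid: Sequence[GridPoint]) -> Iterator[GridPoint]:
    return (g for g in grid if g.included)


def required_production(total_demand: float, survival: float) -> float:
    """Units that must be produced so that ``survival * produced = demand``."""
    if total_demand < 0.0:
        raise ValueError(f"demand must be non-negative, got {total_demand}")
    if total_demand == 0.0:
        return 0.0
    if survival <= 0.0:
        raise UndefinedProductionError(
            f"survival must be positive to meet demand {total_demand}, got {survival}"
        )
    return total_demand / survival
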