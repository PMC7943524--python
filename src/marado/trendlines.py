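"""Homologous-series trendlines of CCS and RT for candidate validation.

Within a lipid class, members of a homologous series (same double-bond count
and adduct, differing only in total acyl carbons) show a linear increase of
CCS with chain length and a typically quadratic retention-time trend on the
reversed-phase gradient.  A candidate whose measured RT and CCS fall on the
trendlines fitted through authentic standards gains orthogonal evidence for
its annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HomologSeriesKey",
    "TrendlineModel",
    "TrendlineVerdict",
    "fit_trend",
    "predict",
    "validate_candidate",
    "auto_form",
]

#: default acceptance tolerances, from the observed error bounds of matched species
DEFAULT_RT_TOLERANCE = 0.02  # 2 % relative
DEFAULT_CCS_TOLERANCE = 0.004  # 0.4 % relative


@dataclass(frozen=True)
class HomologSeriesKey:
    """Identifies one homologous series: class, double-bond count, adduct."""

    lipid_class: str
    double_bonds: int
    adduct: str


@dataclass(frozen=True)
class TrendlineModel:
    series: HomologSeriesKey | None
    form: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]  # highest power first (numpy convention)
    r_squared: float
    n_points: int
    x_min: float
    x_max: float

    @property
    def slope(self) -> float:
        """Leading linear slope (for a quadratic, the derivative at the range midpoint)."""
        if self.form == "linear":
            return self.coefficients[0]
        a, b, _ = self.coefficients
        return 2 * a * (self.x_min + self.x_max) / 2 + b


def auto_form(n_points: int) -> str:
    """Quadratic when at least 4 distinct predictor values are available, else linear.

    RT trends along a homologous series are typically curved, but the few
    standards per series rarely over-determine a quadratic; with fewer than
    four distinct chain lengths the fit falls back to a line.
    """
    return "quadratic" if n_points >= 4 else "linear"


def fit_trend(
    points: Sequence[tuple[float, float]],
    form: str = "linear",
    series: HomologSeriesKey | None = None,
) -> TrendlineModel:
    """Least-squares trendline through (carbons, value) points."""
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown model form: {form!r}")
    degree = 1 if form == "linear" else 2
    if len(points) < degree + 1:
        raise ValueError(
            f"{form} trendline needs >= {degree + 1} points, got {len(points)}"
        )
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    coeffs = np.polyfit(x, y, degree)
    yhat = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TrendlineModel(
        series=series,
        form=form,
        coefficients=tuple(float(c) for c in coeffs),
        r_squared=min(r2, 1.0),
        n_points=len(points),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def predict(model: TrendlineModel, carbons: float) -> tuple[float, bool]:
    """Evaluate the trendline; the flag marks extrapolation beyond the fitted range."""
    value = float(np.polyval(np.array(model.coefficients), carbons))
    extrapolated = carbons < model.x_min or carbons > model.x_max
    return value, extrapolated


@dataclass(frozen=True)
class TrendlineVerdict:
    """Per-dimension relative errors and the combined support decision."""

    supported: bool
    rt_error: float | None
    ccs_error: float | None
    has_model: bool
    extrapolated: bool = False


def validate_candidate(
    carbons: float,
    measured_rt: float | None,
    measured_ccs: float | None,
    rt_model: TrendlineModel | None,
    ccs_model: TrendlineModel | None,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
    ccs_tolerance: float = DEFAULT_CCS_TOLERANCE,
) -> TrendlineVerdict:
    """Check a candidate's RT and CCS against its series trendlines.

    ``supported`` requires every dimension for which both a model and a
    measurement exist to lie within its relative tolerance; with no model at
    all the verdict is "no model" (``has_model=False``, not supported).
    """
    rt_err = ccs_err = None
    extrapolated = False
    checks: list[bool] = []
    if rt_model is not None and measured_rt is not None:
        pred, ex = predict(rt_model, carbons)
        extrapolated |= ex
        rt_err = abs(measured_rt - pred) / abs(pred)
        checks.append(rt_err <= rt_tolerance)
    if ccs_model is not None and measured_ccs is not None:
        pred, ex = predict(ccs_model, carbons)
        extrapolated |= ex
        ccs_err = abs(measured_ccs - pred) / abs(pred)
        checks.append(ccs_err <= ccs_tolerance)
    if not checks:
        return TrendlineVerdict(False, None, None, has_model=False)
    return TrendlineVerdict(
        supported=all(checks),
        rt_error=rt_err,
        ccs_error=ccs_err,
        has_model=True,
        extrapolated=extrapolated,
    )
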