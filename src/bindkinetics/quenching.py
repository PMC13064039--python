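"""Stern–Volmer quenching analysis.

Fluorescence quenching of the protein by the titrated ligand follows

    F₀/F = 1 + K_SV·[Q]

where K_SV (L·mol⁻¹) is the Stern–Volmer constant and the apparent
bimolecular quenching rate constant is K_q = K_SV/τ₀, with τ₀ the
unquenched fluorophore lifetime (10⁻⁸ s for serum albumin).

The quenching mechanism is classified from the temperature dependence of
K_SV together with the magnitude of K_q: a ground-state complex (static
quenching) gives K_SV decreasing with temperature and K_q far above the
diffusion-controlled limit (~2×10¹⁰ L·mol⁻¹·s⁻¹), while collisional
(dynamic) quenching gives the opposite signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_spectra import AnalysisError, TitrationSeries

__all__ = [
    "DIFFUSION_LIMIT_KQ",
    "QuenchingFit",
    "MechanismCall",
    "fit_stern_volmer",
    "classify_mechanism",
]

#: maximum diffusion-controlled quenching rate constant, L·mol⁻¹·s⁻¹
DIFFUSION_LIMIT_KQ = 2e10


@dataclass(frozen=True)
class QuenchingFit:
    """Result of a Stern–Volmer regression at one temperature."""

    ksv: float  # L·mol⁻¹
    kq: float  # L·mol⁻¹·s⁻¹, = ksv / tau0
    tau0: float  # s
    intercept: float
    r_squared: float
    slope_se: float  # standard error of the regression slope
    temperature: float  # K
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise AnalysisError("insufficient titration: need >= 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise AnalysisError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification and the evidence behind it."""

    mechanism: str  # static | dynamic | mixed | indeterminate
    ksv_trend: str  # decreasing | increasing | non-monotonic | single-T
    kq_exceeds_limit: bool
    limit: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on x -> (slope, intercept, r_squared, slope_se).

    Handles the degenerate zero-variance-response case (perfect flat fit)
    that scipy's linregress reports as r = nan.
    """
    if np.allclose(y, y[0], rtol=0.0, atol=0.0):
        return 0.0, float(y[0]), 1.0, 0.0
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return float(res.slope), float(res.intercept), r2, float(res.stderr)


def fit_stern_volmer(
    series: TitrationSeries,
    tau0: float = 1e-8,
    fix_intercept: bool = False,
    intercept_tol: float = 0.05,
) -> QuenchingFit:
    """Fit F₀/F against [Q] by ordinary least squares.

    The slope is K_SV and K_q = K_SV/τ₀. The intercept is free by default
    (robust to small normalization error in F₀); a fitted intercept deviating
    from 1 by more than ``intercept_tol`` (fractional) triggers a diagnostics
    warning, not an error. ``fix_intercept=True`` constrains the line through
    the theoretical intercept of 1. The [Q]=0 point contributes the trivial
    (0, 1) datum and is included.
    """
    if tau0 <= 0:
        raise AnalysisError("tau0 must be positive")
    if len(series) < 3:
        raise AnalysisError("insufficient titration: need >= 3 points")
    f = series.intensities
    if np.any(f == 0):
        raise AnalysisError("zero intensity")
    f0 = series.f0
    x = series.concentrations
    y = f0 / f

    if fix_intercept:
        # least squares of (y - 1) on x with no intercept
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            raise AnalysisError("insufficient titration: no nonzero [Q]")
        slope = float(np.sum(x * (y - 1.0)) / sxx)
        intercept = 1.0
        resid = y - (1.0 + slope * x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
        dof = len(x) - 1
        slope_se = float(np.sqrt(ss_res / dof / sxx)) if dof > 0 else 0.0
    else:
        slope, intercept, r2, slope_se = _ols(x, y)
        if abs(intercept - 1.0) > intercept_tol:
            warnings.warn(
                f"Stern-Volmer intercept {intercept:.4f} deviates from 1 by more "
                f"than {intercept_tol:.0%}; check F0 normalization",
                stacklevel=2,
            )

    return QuenchingFit(
        ksv=slope,
        kq=slope / tau0,
        tau0=tau0,
        intercept=intercept,
        r_squared=r2,
        slope_se=slope_se,
        temperature=series.temperature,
        n_points=len(series),
    )


def _trend(values: list[float]) -> str:
    if len(values) == 1:
        return "single-T"
    diffs = np.diff(values)
    if np.all(diffs < 0):
        return "decreasing"
    if np.all(diffs > 0):
        return "increasing"
    return "non-monotonic"  # ties count as non-monotonic (strict ordering)


def classify_mechanism(
    fits: list[QuenchingFit], kq_limit: float = DIFFUSION_LIMIT_KQ
) -> MechanismCall:
    """Classify the quenching mechanism from per-temperature fits.

    Rule: K_SV strictly decreasing with T and every K_q above the diffusion
    limit → static; strictly increasing with every K_q at or below the limit
    → dynamic; a strict trend with the wrong K_q magnitude → mixed;
    non-monotonic → indeterminate. A single temperature is classified on K_q
    alone (static if above the limit, else indeterminate).
    """
    if not fits:
        raise AnalysisError("no fits supplied")
    ordered = sorted(fits, key=lambda fit: fit.temperature)
    temps = [fit.temperature for fit in ordered]
    if len(set(temps)) != len(temps):
        raise AnalysisError("invalid temperature ladder: duplicate temperatures")

    trend = _trend([fit.ksv for fit in ordered])
    exceeds = all(fit.kq > kq_limit for fit in ordered)

    if trend == "single-T":
        mechanism = "static" if exceeds else "indeterminate"
    elif trend == "decreasing":
        mechanism = "static" if exceeds else "mixed"
    elif trend == "increasing":
        mechanism = "mixed" if exceeds else "dynamic"
    else:
        mechanism = "indeterminate"

    return MechanismCall(
        mechanism=mechanism, ksv_trend=trend, kq_exceeds_limit=exceeds, limit=kq_limit
    )
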