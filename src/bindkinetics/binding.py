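"""Double-logarithmic (modified Stern–Volmer) binding analysis.

For static quenching via an n:1 ligand–protein complex the quenched
fraction obeys

    log₁₀((F₀ − F)/F) = log₁₀ K_b + n·log₁₀[Q]

so an OLS line of the double-log plot yields the binding constant K_b
(intercept, as log₁₀ K_b) and the apparent number of binding sites n
(slope). Base-10 logarithms throughout; K_b in L·mol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_spectra import AnalysisError, TitrationSeries
from .quenching import _ols

__all__ = [
    "BindingFit",
    "StoichiometryCall",
    "fit_double_log",
    "interpret_stoichiometry",
]


@dataclass(frozen=True)
class BindingFit:
    """Result of a double-log binding regression at one temperature.

    ``kb`` is always 10**``log_kb``; points unusable on the log scale
    ([Q]=0, or intensity not strictly quenched/positive) are excluded and
    listed with reasons so every input point is accounted for.
    """

    log_kb: float  # log10(L·mol⁻¹)
    kb: float  # L·mol⁻¹
    n_sites: float
    r_squared: float
    slope_se: float
    temperature: float  # K
    n_points_used: int
    excluded_points: tuple[tuple[float, str], ...] = ()  # (conc, reason)

    def __post_init__(self) -> None:
        if not np.isclose(self.kb, 10.0**self.log_kb, rtol=1e-12):
            raise AnalysisError("kb and log_kb are inconsistent")

    @classmethod
    def from_log_kb(
        cls, log_kb: float, temperature: float = 303.0, n_sites: float = 1.0,
        r_squared: float = 1.0, slope_se: float = 0.0, n_points_used: int = 3,
    ) -> "BindingFit":
        """Build a fit record from a known log₁₀ K_b (e.g. a published table
        row), for comparisons that only need the constant."""
        return cls(
            log_kb=float(log_kb),
            kb=10.0 ** float(log_kb),
            n_sites=n_sites,
            r_squared=r_squared,
            slope_se=slope_se,
            temperature=temperature,
            n_points_used=n_points_used,
        )


@dataclass(frozen=True)
class StoichiometryCall:
    """Interpretation of the fitted site number and binding-constant band."""

    ratio: str  # e.g. "1:1" or "non-integer (n = 0.57)"
    n_sites: float
    affinity: str  # weak-to-moderate | moderate-to-strong | strong
    kb: float


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """OLS of log₁₀((F₀−F)/F) on log₁₀[Q] over the informative points.

    Informative points have [Q] > 0 and 0 < F < F₀; all others are excluded
    with a reason. At least three informative points are required.
    """
    f0 = series.f0
    used_x, used_y = [], []
    excluded: list[tuple[float, str]] = []
    for p in series.points:
        if p.quencher_conc == 0.0:
            excluded.append((p.quencher_conc, "zero concentration"))
        elif p.f_obs <= 0.0:
            excluded.append((p.quencher_conc, "non-positive intensity"))
        elif p.f_obs >= f0:
            excluded.append((p.quencher_conc, "non-positive quenched fraction"))
        else:
            used_x.append(np.log10(p.quencher_conc))
            used_y.append(np.log10((f0 - p.f_obs) / p.f_obs))
    if len(used_x) < 3:
        raise AnalysisError("insufficient informative points")

    slope, intercept, r2, slope_se = _ols(np.array(used_x), np.array(used_y))
    return BindingFit(
        log_kb=intercept,
        kb=10.0**intercept,
        n_sites=slope,
        r_squared=r2,
        slope_se=slope_se,
        temperature=series.temperature,
        n_points_used=len(used_x),
        excluded_points=tuple(excluded),
    )


def interpret_stoichiometry(fit: BindingFit, tol: float = 0.15) -> StoichiometryCall:
    """Report the nearest integer ligand:protein ratio and an affinity band.

    The ratio is 1:round(n) when n is within ``tol`` of an integer, else
    reported as non-integer. Affinity bands on K_b (L·mol⁻¹): below 10⁴
    weak-to-moderate, 10⁴–10⁶ moderate-to-strong, above 10⁶ strong.
    """
    if fit.n_sites <= 0:
        raise AnalysisError("invalid fit: non-positive site number")
    nearest = round(fit.n_sites)
    if nearest >= 1 and abs(fit.n_sites - nearest) <= tol:
        ratio = f"1:{nearest}"
    else:
        ratio = f"non-integer (n = {fit.n_sites:.2f})"
    if fit.kb < 1e4:
        affinity = "weak-to-moderate"
    elif fit.kb <= 1e6:
        affinity = "moderate-to-strong"
    else:
        affinity = "strong"
    return StoichiometryCall(ratio=ratio, n_sites=fit.n_sites, affinity=affinity, kb=fit.kb)
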