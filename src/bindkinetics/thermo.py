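"""van't Hoff thermodynamics and binding-force classification.

The temperature dependence of the binding constant gives the enthalpy and
entropy of complex formation:

    ln K_b = −ΔH/(R·T) + ΔS/R          (van't Hoff)
    ΔG(T)  = ΔH − T·ΔS                 (Gibbs–Helmholtz)

with R = 8.314 J·mol⁻¹·K⁻¹ and K_b treated as dimensionless inside the
logarithm (implicit 1 mol·L⁻¹ standard state). Public values are in kJ.

The signs of (ΔH, ΔS) indicate the dominant intermolecular force
(Ross–Subramanian reading): both positive → hydrophobic association; both
negative → hydrogen bonding / van der Waals; ΔH ≈ 0 with ΔS > 0 →
electrostatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import BindingFit
from .core_spectra import AnalysisError
from .quenching import _ols

__all__ = [
    "GAS_CONSTANT",
    "VantHoffFit",
    "ThermoResult",
    "fit_vant_hoff",
    "gibbs_free_energy",
    "classify_forces",
    "thermo_pipeline",
]

#: molar gas constant, J·mol⁻¹·K⁻¹
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class VantHoffFit:
    delta_h: float  # kJ·mol⁻¹
    delta_s: float  # kJ·mol⁻¹·K⁻¹
    r_squared: float
    slope_se: float
    two_point: bool  # R² = 1 by construction when only 2 temperatures


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic characterization of the binding across a temperature ladder."""

    delta_h: float  # kJ·mol⁻¹
    delta_s: float  # kJ·mol⁻¹·K⁻¹
    delta_g_by_T: dict[float, float]  # K → kJ·mol⁻¹
    r_squared: float
    force_class: str  # hydrophobic | hbond_vdw | electrostatic | mixed
    endothermic: bool
    spontaneous_at: tuple[float, ...]  # temperatures (K) with ΔG < 0
    two_point: bool = False


def fit_vant_hoff(kb_by_T: list[tuple[float, float]]) -> VantHoffFit:
    """OLS of ln K_b on 1/T → (ΔH, ΔS) in kJ units.

    ΔH = −slope·R, ΔS = intercept·R. With exactly two temperatures the line
    is exact and the ``two_point`` flag marks the fit as unvalidated.
    """
    if len(kb_by_T) < 2:
        raise AnalysisError(">= 2 temperatures required")
    temps = [t for t, _ in kb_by_T]
    if len(set(temps)) != len(temps):
        raise AnalysisError("degenerate ladder: duplicate temperatures")
    for t, kb in kb_by_T:
        if t <= 0:
            raise AnalysisError("temperature must be positive (kelvin)")
        if kb <= 0:
            raise AnalysisError("invalid constant: kb must be positive")

    x = np.array([1.0 / t for t, _ in kb_by_T])
    y = np.array([np.log(kb) for _, kb in kb_by_T])
    slope, intercept, r2, slope_se = _ols(x, y)
    two_point = len(kb_by_T) == 2
    if two_point:
        r2 = 1.0
    return VantHoffFit(
        delta_h=-slope * GAS_CONSTANT / 1000.0,
        delta_s=intercept * GAS_CONSTANT / 1000.0,
        r_squared=r2,
        slope_se=slope_se,
        two_point=two_point,
    )


def gibbs_free_energy(delta_h: float, delta_s: float, temperature: float) -> float:
    """ΔG = ΔH − T·ΔS, all in kJ units (ΔS in kJ·mol⁻¹·K⁻¹)."""
    if temperature <= 0:
        raise AnalysisError("temperature must be positive (kelvin)")
    return delta_h - temperature * delta_s


def classify_forces(delta_h: float, delta_s: float, h_tol: float = 4.0) -> str:
    """Map the signs of (ΔH, ΔS) to the dominant binding force.

    ΔH > h_tol with ΔS > 0 → hydrophobic; ΔH < −h_tol with ΔS < 0 →
    hydrogen bond / van der Waals; |ΔH| ≤ h_tol with ΔS > 0 → electrostatic;
    anything else → mixed. ``h_tol`` (kJ·mol⁻¹) quantifies "ΔH ≈ 0".
    """
    if abs(delta_h) <= h_tol:
        return "electrostatic" if delta_s > 0 else "mixed"
    if delta_h > h_tol and delta_s > 0:
        return "hydrophobic"
    if delta_h < -h_tol and delta_s < 0:
        return "hbond_vdw"
    return "mixed"


def thermo_pipeline(binding_fits: list[BindingFit], h_tol: float = 4.0) -> ThermoResult:
    """van't Hoff fit over per-temperature binding fits, ΔG at each input
    temperature, force classification and spontaneity flags."""
    if len(binding_fits) < 2:
        raise AnalysisError(">= 2 temperatures required")
    ordered = sorted(binding_fits, key=lambda f: f.temperature)
    vh = fit_vant_hoff([(f.temperature, f.kb) for f in ordered])
    delta_g = {
        f.temperature: gibbs_free_energy(vh.delta_h, vh.delta_s, f.temperature)
        for f in ordered
    }
    return ThermoResult(
        delta_h=vh.delta_h,
        delta_s=vh.delta_s,
        delta_g_by_T=delta_g,
        r_squared=vh.r_squared,
        force_class=classify_forces(vh.delta_h, vh.delta_s, h_tol=h_tol),
        endothermic=vh.delta_h > 0,
        spontaneous_at=tuple(t for t, g in delta_g.items() if g < 0),
        two_point=vh.two_point,
    )
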