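"""Secondary spectroscopic evidence for the binding interaction.

Three modalities corroborate the quenching analysis:

* **Synchronous fluorescence** — scanning with a fixed excitation–emission
  offset Δλ isolates tyrosine (Δλ = 15 nm) or tryptophan (Δλ = 60 nm)
  residues; a drift of the band maximum under titration signals a polarity
  change in that residue's microenvironment.
* **FTIR amide bands** — amide I (1600–1700 cm⁻¹, mainly C=O stretch) is
  sensitive to protein secondary structure; a shift between the free and
  complexed protein indicates a conformational change. Amide II
  (1500–1600 cm⁻¹) is reported alongside.
* **UV-vis titration** — the ~220 nm band tracks the α-helical backbone and
  the ~280 nm band the aromatic residues; intensity/position changes under
  titration are expected for static (ground-state complex) quenching but not
  for purely collisional quenching. The 280 nm band also yields the molar
  absorptivity ε = A/(c·l) via Beer–Lambert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_spectra import (
    AnalysisError,
    PeakResult,
    ShiftRecord,
    Spectrum,
    locate_peak,
    peak_shift,
)
from .quenching import MechanismCall

__all__ = [
    "SynchronousSeries",
    "ModalityReport",
    "UVFeatures",
    "AMIDE_I_WINDOW",
    "AMIDE_II_WINDOW",
    "UV_HELIX_WINDOW",
    "UV_AROMATIC_WINDOW",
    "SYNCHRONOUS_WINDOW",
    "synchronous_shift",
    "amide_band_shift",
    "uv_titration_features",
    "corroborate_mechanism",
]

AMIDE_I_WINDOW = (1600.0, 1700.0)
AMIDE_II_WINDOW = (1500.0, 1600.0)
UV_HELIX_WINDOW = (210.0, 235.0)
UV_AROMATIC_WINDOW = (260.0, 300.0)
SYNCHRONOUS_WINDOW = (260.0, 320.0)


@dataclass
class SynchronousSeries:
    """Synchronous spectra at one Δλ offset across the titration."""

    delta_lambda: float  # nm; 15 (Tyr) or 60 (Trp) by convention
    spectra: list[Spectrum]
    quencher_concs: list[float]  # mol·L⁻¹, one per spectrum
    allowed_offsets: tuple[float, ...] = (15.0, 60.0)

    def __post_init__(self) -> None:
        if self.allowed_offsets and self.delta_lambda not in self.allowed_offsets:
            raise AnalysisError(
                f"unsupported synchronous offset {self.delta_lambda} nm"
            )
        if len(self.spectra) != len(self.quencher_concs):
            raise AnalysisError("spectra count differs from concentration count")


@dataclass(frozen=True)
class ModalityReport:
    """One band-shift observation with its standard interpretation."""

    residue: str  # Trp | Tyr | amideI | amideII | uv_band
    shift: float  # axis units, treated − reference
    direction: str  # red | blue | none
    interpretation: str
    reference_peak: PeakResult | None = None
    treated_peak: PeakResult | None = None
    trend: tuple[tuple[float, float], ...] = ()  # (conc, peak position) per point


@dataclass(frozen=True)
class UVFeatures:
    """Per-titration-point UV band features and the overall trends."""

    band_220: tuple[PeakResult, ...]
    band_280: tuple[PeakResult, ...]
    position_trend_220: ShiftRecord
    intensity_change_220: float  # last − first peak height
    epsilon_279: float  # M⁻¹·cm⁻¹, from the highest-concentration spectrum
    spectra_changed: bool  # any band intensity/position response to titration


_RESIDUE_BY_OFFSET = {60.0: "Trp", 15.0: "Tyr"}


def synchronous_shift(
    series: SynchronousSeries, window: tuple[float, float] = SYNCHRONOUS_WINDOW
) -> ModalityReport:
    """Band shift between the zero-quencher and highest-quencher spectra.

    Reports the signed drift of the synchronous band maximum; a shift at or
    beyond the grid resolution is read as a microenvironment change near the
    residue the Δλ offset selects (Trp for 60 nm, Tyr for 15 nm).
    """
    if len(series.spectra) < 2:
        raise AnalysisError("need >= 2 synchronous spectra")
    order = np.argsort(series.quencher_concs)
    first = series.spectra[order[0]]
    last = series.spectra[order[-1]]
    ref = locate_peak(first, window)
    treated = locate_peak(last, window)
    rec = peak_shift(ref, treated)
    residue = _RESIDUE_BY_OFFSET.get(series.delta_lambda, f"dl={series.delta_lambda:g}")
    if rec.direction == "none":
        interp = f"no microenvironment change near {residue}"
    else:
        interp = f"microenvironment change near {residue} ({rec.direction} shift)"
    trend = tuple(
        (series.quencher_concs[i], locate_peak(series.spectra[i], window).position)
        for i in order
    )
    return ModalityReport(
        residue=residue,
        shift=rec.shift,
        direction=rec.direction,
        interpretation=interp,
        reference_peak=ref,
        treated_peak=treated,
        trend=trend,
    )


def amide_band_shift(free: Spectrum, complexed: Spectrum) -> list[ModalityReport]:
    """Amide I and amide II peak shifts between free and complexed protein.

    Both spectra must be on a wavenumber axis covering 1500–1700 cm⁻¹; the
    amide I shift, when beyond the grid resolution, is interpreted as a
    secondary-structure change.
    """
    for s in (free, complexed):
        if s.axis_kind != "ftir_wavenumber":
            raise AnalysisError("incomparable spectra: expected ftir_wavenumber axis")
        lo, hi = float(np.min(s.axis)), float(np.max(s.axis))
        if lo > AMIDE_II_WINDOW[0] or hi < AMIDE_I_WINDOW[1]:
            raise AnalysisError("band window not covered")

    reports = []
    for name, window in (("amideI", AMIDE_I_WINDOW), ("amideII", AMIDE_II_WINDOW)):
        ref = locate_peak(free, window)
        treated = locate_peak(complexed, window)
        rec = peak_shift(ref, treated)
        if name == "amideI" and rec.direction != "none":
            interp = "secondary-structure change"
        elif rec.direction != "none":
            interp = f"{name} band shift"
        else:
            interp = "no change"
        reports.append(
            ModalityReport(
                residue=name,
                shift=rec.shift,
                direction=rec.direction,
                interpretation=interp,
                reference_peak=ref,
                treated_peak=treated,
            )
        )
    return reports


def uv_titration_features(
    spectra: list[Spectrum],
    protein_conc: float,
    path_cm: float = 1.0,
    intensity_rel_tol: float = 0.01,
) -> UVFeatures:
    """Extract UV-vis band features across the titration.

    Locates the ~220 nm (helix) and ~280 nm (aromatic) bands in every
    spectrum, reports the position/intensity trend of the 220 nm band between
    the first and last titration points, and computes the molar absorptivity
    ε = A(≈279 nm)/(c·l) from the highest-concentration spectrum. Spectra are
    expected in ascending titration order (``meta`` concentrations are used
    to sort when present).
    """
    if protein_conc <= 0 or path_cm <= 0:
        raise AnalysisError("invalid Beer-Lambert input")
    if not spectra:
        raise AnalysisError("no spectra supplied")
    if all(isinstance(s.meta, float) for s in spectra):
        spectra = sorted(spectra, key=lambda s: s.meta)

    band220 = tuple(locate_peak(s, UV_HELIX_WINDOW) for s in spectra)
    band280 = tuple(locate_peak(s, UV_AROMATIC_WINDOW) for s in spectra)

    pos_trend = peak_shift(band220[0], band220[-1])
    dI = band220[-1].height - band220[0].height
    ref_height = band220[0].height
    intensity_changed = abs(dI) > intensity_rel_tol * max(ref_height, 1e-30)
    changed = intensity_changed or pos_trend.direction != "none"

    epsilon = band280[-1].height / (protein_conc * path_cm)
    return UVFeatures(
        band_220=band220,
        band_280=band280,
        position_trend_220=pos_trend,
        intensity_change_220=float(dI),
        epsilon_279=float(epsilon),
        spectra_changed=changed,
    )


def corroborate_mechanism(uv_features: UVFeatures, mechanism: MechanismCall) -> str:
    """Check the UV response against the quenching-mechanism call.

    Ground-state complex formation (static quenching) perturbs the protein's
    absorption spectrum; collisional quenching does not. Returns
    "consistent", "inconsistent" or "ambiguous".
    """
    changed = uv_features.spectra_changed
    call = mechanism.mechanism
    if changed and call == "static":
        return "consistent"
    if changed and call == "dynamic":
        return "inconsistent"
    if not changed and call == "dynamic":
        return "consistent"
    return "ambiguous"
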