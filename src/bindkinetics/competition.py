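"""Site-marker competitive displacement and metal-ion modulation analysis.

Serum albumin binds small ligands mainly at Sudlow site I (subdomain IIA,
probed by phenylbutazone) and site II (subdomain IIIA, probed by diazepam).
If a site marker occupies the ligand's site, the apparent binding constant
drops; comparing log K_b with and without each probe therefore assigns the
site. Metal ions modulate the interaction analogously: the ratio of K_b
with and without the ion labels it as enhancing, reducing, or neutral.

Comparisons operate on log₁₀ K_b (regression intercepts), which is
symmetric under rescaling and matches how binding tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binding import BindingFit
from .core_spectra import AnalysisError

__all__ = [
    "ConditionFit",
    "SiteCall",
    "MetalEffect",
    "MetalModulationReport",
    "assign_site",
    "metal_modulation",
]

_SITE_ROLES = {"site_I_probe", "site_II_probe", "metal", "blank", "other"}
_SITE_BY_ROLE = {"site_I_probe": "site_I", "site_II_probe": "site_II"}


@dataclass(frozen=True)
class ConditionFit:
    """A binding fit obtained under one experimental condition."""

    condition: str  # e.g. blank, phenylbutazone, diazepam, Na+, Ca2+
    site_role: str  # site_I_probe | site_II_probe | metal | blank | other
    fit: BindingFit

    def __post_init__(self) -> None:
        if self.site_role not in _SITE_ROLES:
            raise AnalysisError(f"unknown site role {self.site_role!r}")


@dataclass(frozen=True)
class SiteCall:
    """Binding-site assignment from competitive displacement."""

    assigned_site: str  # site_I | site_II | both | indeterminate
    delta_log_kb_by_condition: dict[str, float]  # blank − probe
    threshold: float


@dataclass(frozen=True)
class MetalEffect:
    condition: str
    ratio: float  # kb(metal) / kb(blank)
    delta_log_kb: float  # log_kb(metal) − log_kb(blank)
    label: str  # enhanced | reduced | unchanged


@dataclass(frozen=True)
class MetalModulationReport:
    effects: tuple[MetalEffect, ...]
    threshold: float
    blank_log_kb: float


def _find_blank(fits: list[ConditionFit]) -> ConditionFit:
    blanks = [f for f in fits if f.site_role == "blank"]
    if not blanks:
        raise AnalysisError("missing reference condition")
    if len(blanks) > 1:
        raise AnalysisError("ambiguous reference: multiple blank conditions")
    return blanks[0]


def assign_site(fits: list[ConditionFit], threshold: float = 0.2) -> SiteCall:
    """Assign the binding site from probe-displacement fits.

    For each site probe, Δ = log K_b(blank) − log K_b(probe); a probe whose
    presence drops the constant by at least ``threshold`` log units marks its
    site as the ligand's. Both probes responding → "both"; none →
    "indeterminate".
    """
    blank = _find_blank(fits)
    probes = [f for f in fits if f.site_role in _SITE_BY_ROLE]
    if not probes:
        raise AnalysisError("no probe condition supplied")

    deltas = {p.condition: blank.fit.log_kb - p.fit.log_kb for p in probes}
    hit_sites = sorted(
        {_SITE_BY_ROLE[p.site_role] for p in probes if deltas[p.condition] >= threshold}
    )
    if not hit_sites:
        assigned = "indeterminate"
    elif len(hit_sites) == 1:
        assigned = hit_sites[0]
    else:
        assigned = "both"
    return SiteCall(
        assigned_site=assigned, delta_log_kb_by_condition=deltas, threshold=threshold
    )


def metal_modulation(
    fits: list[ConditionFit], threshold: float = 0.15
) -> MetalModulationReport:
    """Label each metal-ion condition by its effect on the binding constant.

    Δlog K_b at or above ``threshold`` → enhanced, at or below −threshold →
    reduced, otherwise unchanged; the K_b ratio is reported alongside.
    """
    blank = _find_blank(fits)
    metals = [f for f in fits if f.site_role == "metal"]
    if not metals:
        raise AnalysisError("no metal condition supplied")

    effects = []
    for m in sorted(metals, key=lambda f: f.condition):
        dlog = m.fit.log_kb - blank.fit.log_kb
        if dlog >= threshold:
            label = "enhanced"
        elif dlog <= -threshold:
            label = "reduced"
        else:
            label = "unchanged"
        effects.append(
            MetalEffect(
                condition=m.condition,
                ratio=m.fit.kb / blank.fit.kb,
                delta_log_kb=dlog,
                label=label,
            )
        )
    return MetalModulationReport(
        effects=tuple(effects), threshold=threshold, blank_log_kb=blank.fit.log_kb
    )
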