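"""Shared fixtures: reference constants of the albumin–ligand study and
noise-free synthetic bundles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import bindkinetics as bk

# Published reference values of the serum-albumin / antihistamine system the
# defaults emulate (used as ground truth for round-trip tests).
KSV_BY_T = {303.0: 1.07e4, 310.0: 0.82e4, 318.0: 0.48e4}  # L/mol
LOG_KB_BY_T = {303.0: 2.55, 310.0: 3.18, 318.0: 3.95}
N_BY_T = {303.0: 0.57, 310.0: 0.83, 318.0: 1.06}
DELTA_H = 133.024  # kJ/mol
DELTA_S = 0.487  # kJ/mol/K
TAU0 = 1e-8  # s
KQ_LIMIT = 2e10  # L/mol/s

SITE_TABLE = {"blank": 2.55, "phenylbutazone": 1.91, "diazepam": 2.50}
METAL_TABLE = {
    "Na+": 2.27,
    "K+": 3.74,
    "Mg2+": 3.28,
    "Ca2+": 4.15,
    "Zn2+": 3.77,
    "Fe3+": 2.58,
}


@pytest.fixture(scope="session")
def sv_series():
    """Noise-free Stern-Volmer titration at 303 K with K_SV = 1.07e4."""
    cfg = bk.SyntheticConfig(mode="stern_volmer", ksv=KSV_BY_T[303.0], temperatures=(303.0,))
    return bk.generate_titration(cfg).series_by_T[303.0]


@pytest.fixture(scope="session")
def sv_ladder():
    """Noise-free Stern-Volmer series at all three temperatures, each
    generated with its published K_SV."""
    cfg = bk.SyntheticConfig(
        mode="stern_volmer", ksv=dict(KSV_BY_T), temperatures=tuple(KSV_BY_T)
    )
    return bk.generate_titration(cfg).series_by_T


@pytest.fixture(scope="session")
def thermo_bundle():
    """Noise-free double-log ladder driven by the published (dH, dS)."""
    cfg = bk.SyntheticConfig(
        mode="double_log", ksv=None, delta_h=DELTA_H, delta_s=DELTA_S, n_sites=1.0
    )
    return bk.generate_titration(cfg)


@pytest.fixture(scope="session")
def spectra_bundle():
    """Deterministic multi-modality spectra with the default band layout."""
    return bk.generate_spectra(bk.SyntheticConfig(mode="stern_volmer", ksv=KSV_BY_T[303.0]))


def make_series(concs, intensities, temperature=303.0, **kw):
    """Build a TitrationSeries from raw arrays (concs in mol/L)."""
    points = [bk.TitrationPoint(float(c), float(f)) for c, f in zip(concs, intensities)]
    return bk.TitrationSeries(points=points, temperature=temperature, **kw)


def double_log_series(kb, n, f0=641.0, temperature=303.0, concs=None):
    """Noise-free series obeying (F0-F)/F = kb*[Q]^n."""
    if concs is None:
        concs = np.arange(0, 101, 10) * 1e-6
    concs = np.asarray(concs, dtype=float)
    f = f0 / (1.0 + kb * concs**n)
    return make_series(concs, f, temperature=temperature)
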