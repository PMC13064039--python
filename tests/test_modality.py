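"""Synchronous, FTIR and UV-vis spectral evidence analyses."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindkinetics as bk
from bindkinetics.core_spectra import AnalysisError
from bindkinetics.modality import corroborate_mechanism
from bindkinetics.synthetic_data import SpectraParams


def _bundle(**spectra_overrides):
    cfg = bk.SyntheticConfig(mode="stern_volmer", ksv=1.07e4)
    return bk.generate_spectra(cfg, SpectraParams(**spectra_overrides))


class TestSynchronousShift:
    def test_trp_band_red_shift(self, spectra_bundle):
        rep = bk.synchronous_shift(spectra_bundle.spectra["sync60"])
        assert rep.residue == "Trp"
        assert rep.shift == pytest.approx(2.0, abs=0.5)
        assert rep.direction == "red"
        assert "Trp" in rep.interpretation

    def test_tyr_band_stationary(self, spectra_bundle):
        rep = bk.synchronous_shift(spectra_bundle.spectra["sync15"])
        assert rep.residue == "Tyr"
        assert rep.shift == pytest.approx(0.0, abs=0.25)
        assert rep.direction == "none"
        assert "no microenvironment change" in rep.interpretation

    def test_negative_drift_is_blue(self):
        bundle = _bundle(sync60_drift=-3.0)
        rep = bk.synchronous_shift(bundle.spectra["sync60"])
        assert rep.direction == "blue"
        assert rep.shift == pytest.approx(-3.0, abs=0.5)

    @pytest.mark.parametrize("drift", [-4.0, -2.0, 2.0, 5.0])
    def test_programmed_drift_recovered_within_grid_step(self, drift):
        bundle = _bundle(sync60_drift=drift)
        rep = bk.synchronous_shift(bundle.spectra["sync60"])
        grid_step = 1.0
        assert rep.shift == pytest.approx(drift, abs=grid_step)

    def test_trend_table_covers_all_points(self, spectra_bundle):
        rep = bk.synchronous_shift(spectra_bundle.spectra["sync60"])
        assert len(rep.trend) == len(spectra_bundle.spectra["sync60"].spectra)
        positions = [p for _, p in rep.trend]
        assert positions == sorted(positions)  # monotone drift

    def test_single_spectrum_rejected(self, spectra_bundle):
        series = spectra_bundle.spectra["sync60"]
        short = bk.SynchronousSeries(60.0, series.spectra[:1], series.quencher_concs[:1])
        with pytest.raises(AnalysisError, match=">= 2"):
            bk.synchronous_shift(short)


class TestAmideBandShift:
    def test_amide_shift_pair(self, spectra_bundle):
        free = spectra_bundle.spectra["ftir_free"]
        complexed = spectra_bundle.spectra["ftir_complex"]
        reports = {r.residue: r for r in bk.amide_band_shift(free, complexed)}
        assert reports["amideI"].shift == pytest.approx(-4.0, abs=0.5)
        assert reports["amideI"].interpretation == "secondary-structure change"
        assert reports["amideII"].direction == "none"

    def test_identical_spectra_report_no_change(self, spectra_bundle):
        free = spectra_bundle.spectra["ftir_free"]
        for r in bk.amide_band_shift(free, free):
            assert r.shift == 0.0
            assert r.interpretation == "no change"

    def test_antisymmetric_under_swap(self, spectra_bundle):
        free = spectra_bundle.spectra["ftir_free"]
        complexed = spectra_bundle.spectra["ftir_complex"]
        fwd = {r.residue: r.shift for r in bk.amide_band_shift(free, complexed)}
        rev = {r.residue: r.shift for r in bk.amide_band_shift(complexed, free)}
        for band in fwd:
            assert fwd[band] == pytest.approx(-rev[band], abs=1e-9)

    def test_truncated_spectrum_rejected(self, spectra_bundle):
        free = spectra_bundle.spectra["ftir_free"]
        sel = free.axis <= 1650
        truncated = bk.Spectrum("ftir_wavenumber", free.axis[sel], free.intensity[sel])
        with pytest.raises(AnalysisError, match="band window not covered"):
            bk.amide_band_shift(truncated, truncated)


class TestUvTitrationFeatures:
    def test_molar_absorptivity_from_aromatic_band(self, spectra_bundle):
        feats = bk.uv_titration_features(spectra_bundle.spectra["uv"], protein_conc=2e-6)
        # A(279) = 0.112 at 2 uM over 1 cm -> 56,000 / M / cm
        assert feats.epsilon_279 == pytest.approx(56_000, rel=1e-3)

    def test_zero_absorbance_gives_zero_epsilon(self):
        axis = np.arange(190.0, 351.0, 1.0)
        flat = [bk.Spectrum("uv_nm", axis, np.zeros(axis.size), meta=float(i) * 1e-6)
                for i in range(3)]
        feats = bk.uv_titration_features(flat, protein_conc=2e-6)
        assert feats.epsilon_279 == 0.0
        assert not feats.spectra_changed

    def test_helix_band_red_shift_trend(self, spectra_bundle):
        feats = bk.uv_titration_features(spectra_bundle.spectra["uv"], protein_conc=2e-6)
        assert feats.position_trend_220.direction == "red"
        assert feats.intensity_change_220 > 0
        assert feats.spectra_changed

    def test_invalid_beer_lambert_inputs_rejected(self, spectra_bundle):
        with pytest.raises(AnalysisError, match="invalid Beer-Lambert"):
            bk.uv_titration_features(spectra_bundle.spectra["uv"], protein_conc=0.0)
        with pytest.raises(AnalysisError, match="invalid Beer-Lambert"):
            bk.uv_titration_features(spectra_bundle.spectra["uv"], 2e-6, path_cm=-1.0)

    @given(scale=st.floats(0.1, 10.0), conc_factor=st.floats(0.5, 4.0))
    @settings(derandomize=True, max_examples=40)
    def test_beer_lambert_scaling(self, scale, conc_factor, spectra_bundle):
        """epsilon scales linearly with absorbance and inversely with conc."""
        base = spectra_bundle.spectra["uv"]
        scaled = [bk.Spectrum(s.axis_kind, s.axis, s.intensity * scale, s.meta) for s in base]
        f0 = bk.uv_titration_features(base, 2e-6)
        f1 = bk.uv_titration_features(scaled, 2e-6 * conc_factor)
        assert f1.epsilon_279 == pytest.approx(f0.epsilon_279 * scale / conc_factor, rel=1e-9)


class TestCorroborateMechanism:
    def _mech(self, name):
        return bk.MechanismCall(name, "decreasing", True, 2e10)

    def _features(self, changed):
        peak = bk.PeakResult(220.0, 1.0, (210, 235), "uv_nm", 1.0)
        trend = bk.ShiftRecord(2.0 if changed else 0.0, "red" if changed else "none", 0.5, "uv_nm")
        return bk.UVFeatures((peak,), (peak,), trend, 0.5 if changed else 0.0, 56_000.0, changed)

    @pytest.mark.parametrize(
        "changed, mechanism, expected",
        [
            (True, "static", "consistent"),
            (True, "dynamic", "inconsistent"),
            (False, "dynamic", "consistent"),
            (False, "static", "ambiguous"),
            (True, "mixed", "ambiguous"),
        ],
    )
    def test_rule_table(self, changed, mechanism, expected):
        assert corroborate_mechanism(self._features(changed), self._mech(mechanism)) == expected

    def test_full_synthetic_chain_is_consistent(self, sv_ladder, spectra_bundle):
        fits = [bk.fit_stern_volmer(s) for s in sv_ladder.values()]
        call = bk.classify_mechanism(fits)
        assert call.mechanism == "static"
        feats = bk.uv_titration_features(spectra_bundle.spectra["uv"], 2e-6)
        assert corroborate_mechanism(feats, call) == "consistent"
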