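"""Core types, CSV round-trips, inner-filter correction and peak utilities."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindkinetics as bk
from bindkinetics.core_spectra import AnalysisError

from conftest import make_series


class TestInnerFilterCorrection:
    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),  # zero-absorbance identity
            (100.0, 0.42, 0.0, 100.0 * 10**0.21),  # 162.18: maximal reported A_ex
            (50.0, 0.08, 0.08, 50.0 * 10**0.08),  # 60.09: protein-alone absorbance
        ],
    )
    def test_reference_values(self, f_obs, a_ex, a_em, expected):
        assert bk.correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(expected, abs=1e-9)

    def test_maximal_reported_absorbance_correction(self):
        # at the largest excitation-wavelength absorbance of the system (0.42)
        # the correction multiplies the signal by 10^0.21 ≈ 1.6218
        assert bk.correct_inner_filter(100.0, 0.42, 0.0) == pytest.approx(162.18, abs=0.01)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(AnalysisError, match="invalid absorbance"):
            bk.correct_inner_filter(10.0, -0.1, 0.0)

    @given(
        f=st.floats(0.1, 1e4),
        a=st.floats(0.0, 2.0),
        b=st.floats(0.0, 2.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_never_decreasing(self, f, a, b):
        fab = bk.correct_inner_filter(f, a, b)
        assert fab == pytest.approx(bk.correct_inner_filter(f, b, a), rel=1e-12)
        assert fab >= f

    @given(f=st.floats(1.0, 1e3), a=st.floats(0.0, 1.0), da=st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_in_absorbance(self, f, a, da):
        assert bk.correct_inner_filter(f, a + da, 0.0) > bk.correct_inner_filter(f, a, 0.0)


class TestCorrectSeries:
    def test_zero_absorbance_is_identity(self):
        series = make_series([0, 1e-5, 2e-5], [641, 600, 560])
        series = bk.TitrationSeries(
            [bk.TitrationPoint(p.quencher_conc, p.f_obs, 0.0, 0.0) for p in series.points]
        )
        corrected = bk.correct_series(series)
        assert np.allclose(corrected.intensities, series.intensities)
        # originals preserved alongside
        assert all(p.f_raw is not None for p in corrected.points)

    def test_rising_absorbance_gives_monotone_correction_ratio(self):
        a_ex = np.linspace(0.08, 0.42, 5)
        points = [
            bk.TitrationPoint(i * 1e-5, 600.0, float(a), 0.0) for i, a in enumerate(a_ex)
        ]
        corrected = bk.correct_series(bk.TitrationSeries(points))
        ratio = corrected.intensities / np.array([p.f_raw for p in corrected.points])
        assert ratio[0] == pytest.approx(10**0.04)
        assert ratio[-1] == pytest.approx(10**0.21)
        assert np.all(np.diff(ratio) > 0)

    def test_passthrough_warns_and_returns_unchanged(self):
        series = make_series([0, 1e-5, 2e-5], [641, 600, 560])
        with pytest.warns(UserWarning, match="uncorrected"):
            out = bk.correct_series(series, passthrough=True)
        assert np.allclose(out.intensities, series.intensities)

    def test_mixed_absorbance_columns_rejected(self):
        points = [
            bk.TitrationPoint(0.0, 641.0, 0.08, 0.0),
            bk.TitrationPoint(1e-5, 600.0),
            bk.TitrationPoint(2e-5, 560.0, 0.2, 0.0),
        ]
        with pytest.raises(AnalysisError, match="inconsistent absorbance"):
            bk.correct_series(bk.TitrationSeries(points))


class TestTitrationCsv:
    def test_parse_and_units(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("# temperature_K: 303\nconc_uM,F\n0,641\n10,580\n")
        series = bk.read_titration_csv(p)
        assert len(series) == 2
        assert series.f0 == 641.0
        assert series.temperature == 303.0
        assert series.points[1].quencher_conc == pytest.approx(10e-6)

    def test_full_range_spans_1e_minus_4_molar(self, tmp_path):
        rows = "\n".join(f"{c},{641 - c}" for c in range(0, 101, 10))
        p = tmp_path / "t.csv"
        p.write_text("conc_uM,F\n" + rows + "\n")
        series = bk.read_titration_csv(p)
        assert series.concentrations.max() == pytest.approx(1.0e-4)

    @pytest.mark.parametrize(
        "body, msg",
        [
            ("conc_uM,F\n10,580\n20,520\n", "no reference point"),
            ("conc_uM,F\n0,641\n10,580\n10,575\n", "ambiguous titration point"),
            ("conc_uM,F\n0,641\n10,-5\n", "invalid measurement"),
        ],
    )
    def test_ingestion_errors(self, tmp_path, body, msg):
        p = tmp_path / "bad.csv"
        p.write_text(body)
        with pytest.raises(AnalysisError, match=msg):
            bk.read_titration_csv(p)

    def test_write_read_round_trip_full_precision(self, tmp_path, sv_series):
        p = tmp_path / "rt.csv"
        bk.write_titration_csv(sv_series, p)
        back = bk.read_titration_csv(p)
        assert back.temperature == sv_series.temperature
        assert np.array_equal(back.concentrations, sv_series.concentrations)
        assert np.array_equal(back.intensities, sv_series.intensities)

    def test_spectra_csv_round_trip(self, tmp_path, spectra_bundle):
        p = tmp_path / "uv.csv"
        bk.write_spectra_csv(spectra_bundle.spectra["uv"], p)
        back = bk.read_spectra_csv(p)
        orig = spectra_bundle.spectra["uv"]
        assert len(back) == len(orig)
        assert back[0].axis_kind == "uv_nm"
        assert np.array_equal(back[-1].intensity, orig[-1].intensity)
        assert back[-1].meta == pytest.approx(orig[-1].meta)


class TestLocatePeak:
    def _gauss_spectrum(self, center, kind="emission_nm", lo=300, hi=400, step=1.0):
        axis = np.arange(lo, hi + step / 2, step)
        return bk.Spectrum(kind, axis, np.exp(-0.5 * ((axis - center) / 10.0) ** 2))

    @pytest.mark.parametrize("center", [341.0, 341.4, 1642.0])
    def test_symmetric_band_center_within_one_grid_step(self, center):
        if center > 1000:
            spec = self._gauss_spectrum(center, "ftir_wavenumber", 1600, 1700)
            window = (1600, 1700)
        else:
            spec = self._gauss_spectrum(center)
            window = (300, 400)
        peak = bk.locate_peak(spec, window)
        assert peak.position == pytest.approx(center, abs=peak.grid_step)
        assert not peak.flat

    def test_on_grid_center_is_exact(self):
        peak = bk.locate_peak(self._gauss_spectrum(341.0), (300, 400))
        assert peak.position == 341.0

    def test_flat_window_returns_leftmost_with_flag(self):
        axis = np.arange(300, 401, 1.0)
        spec = bk.Spectrum("emission_nm", axis, np.full(axis.size, 5.0))
        peak = bk.locate_peak(spec, (320, 360))
        assert peak.flat
        assert peak.position == 320.0

    def test_window_outside_axis_rejected(self):
        with pytest.raises(AnalysisError, match="window outside axis"):
            bk.locate_peak(self._gauss_spectrum(341.0), (500, 600))


class TestPeakShift:
    def _peak(self, pos, kind="synchronous_nm"):
        return bk.PeakResult(pos, 1.0, (pos - 50, pos + 50), kind, 1.0)

    def test_red_shift_on_nm_axis(self):
        rec = bk.peak_shift(self._peak(339.0), self._peak(341.0))
        assert rec.shift == pytest.approx(2.0)
        assert rec.direction == "red"

    def test_zero_shift_is_none(self):
        rec = bk.peak_shift(self._peak(341.0), self._peak(341.0))
        assert rec.shift == 0.0
        assert rec.direction == "none"

    def test_wavenumber_shift_sign(self):
        rec = bk.peak_shift(
            self._peak(1646.0, "ftir_wavenumber"), self._peak(1642.0, "ftir_wavenumber")
        )
        assert rec.shift == pytest.approx(-4.0)
        assert rec.direction == "red"  # lower wavenumber = lower energy

    def test_subresolution_shift_is_none(self):
        rec = bk.peak_shift(self._peak(341.0), self._peak(341.2))
        assert rec.direction == "none"

    def test_mismatched_axis_kinds_rejected(self):
        with pytest.raises(AnalysisError, match="incomparable spectra"):
            bk.peak_shift(self._peak(341.0), self._peak(341.0, "ftir_wavenumber"))
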