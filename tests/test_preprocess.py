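"""MBLL conversion, band-pass behavior, and the windowed-SD/MAD artifact rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirscreen import (
    MBLLCoefficients,
    bandpass,
    detect_artifact_windows,
    forward_mbll,
    mbll_convert,
)
from fnirscreen.containers import RawRecording
from fnirscreen.preprocess import ConfigurationError, mad_outlier_mask, window_sds
from helpers import FS, make_recording, make_series


class TestMBLL:
    def test_zero_maps_to_zero(self, layout):
        rec = make_recording(np.zeros((48, 2, 50)), layout)
        hemo = mbll_convert(rec)
        assert np.all(hemo.hbo == 0) and np.all(hemo.hbr == 0)

    def test_round_trip_against_independent_solve(self, layout):
        """Forward dOD from known concentrations inverts exactly (1e-10)."""
        coef = MBLLCoefficients.default()
        hbo = np.full((48, 30), 0.01)
        hbr = np.full((48, 30), -0.003)
        rec = make_recording(forward_mbll(hbo, hbr, coef), layout)
        hemo = mbll_convert(rec, coef)
        assert np.max(np.abs(hemo.hbo - 0.01)) < 1e-10
        assert np.max(np.abs(hemo.hbr + 0.003)) < 1e-10
        # independent oracle: solve the 2x2 system per wavelength by hand
        scaled = coef.extinction * coef.pathlengths[:, None]
        od = rec.delta_od[0, :, 0]
        conc = np.linalg.solve(scaled, od)
        assert conc == pytest.approx([0.01, -0.003], abs=1e-12)

    def test_linearity_doubling(self, layout):
        rng = np.random.default_rng(0)
        od = rng.standard_normal((48, 2, 40)) * 1e-3
        h1 = mbll_convert(make_recording(od, layout))
        h2 = mbll_convert(make_recording(2 * od, layout))
        assert np.allclose(h2.hbo, 2 * h1.hbo) and np.allclose(h2.hbr, 2 * h1.hbr)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_inverse_of_forward_is_identity(self, layout, seed):
        """MBLL o forward-MBLL = identity for well-conditioned coefficients."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            ext = rng.uniform(0.2, 2.0, size=(2, 2))
            if np.linalg.cond(ext) < 1e3:
                break
        else:
            return
        coef = MBLLCoefficients(extinction=ext, dpf=tuple(rng.uniform(3, 8, 2)))
        hbo = rng.standard_normal((48, 20)) * 1e-3
        hbr = rng.standard_normal((48, 20)) * 1e-3
        rec = make_recording(forward_mbll(hbo, hbr, coef), layout)
        hemo = mbll_convert(rec, coef)
        assert np.max(np.abs(hemo.hbo - hbo)) < 1e-10
        assert np.max(np.abs(hemo.hbr - hbr)) < 1e-10

    def test_singular_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            MBLLCoefficients(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_wavelength_mismatch_rejected(self, layout):
        rec = RawRecording(
            subject_id="S",
            layout=layout,
            delta_od=np.zeros((48, 2, 10)),
            fs=FS,
            wavelengths=(760.0, 840.0),
        )
        with pytest.raises(ValueError, match="wavelength"):
            mbll_convert(rec)


class TestBandpass:
    def test_dc_removed(self):
        series = make_series(np.full((1, 2441), 3.0), filter_state="raw")
        out = bandpass(series)
        assert np.max(np.abs(out.hbo)) < 0.03  # < 1% of the DC input
        assert np.abs(out.hbo.mean()) < 1e-6 * max(out.hbo.std(), 1e-30)

    @staticmethod
    def _tone_amplitude(x, t, freq):
        """Least-squares amplitude of a tone, robust to filter transients."""
        design = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        return float(np.hypot(*coef))

    def test_cardiac_frequency_attenuated(self):
        """1 Hz tone (cardiac) is suppressed by >= 20 dB in the central segment."""
        t = np.arange(2441) / FS
        series = make_series(np.sin(2 * np.pi * 1.0 * t)[None, :], filter_state="raw")
        out = bandpass(series)
        core = slice(800, -800)  # keep ~100 s clear of edge transients
        amp = self._tone_amplitude(out.hbo[0, core], t[core], 1.0)
        assert amp <= 0.1

    def test_passband_preserved_at_tenth_hz(self):
        """0.1 Hz tone passes within 5% of unit amplitude."""
        t = np.arange(2441) / FS
        series = make_series(np.sin(2 * np.pi * 0.1 * t)[None, :], filter_state="raw")
        out = bandpass(series)
        core = slice(800, -800)
        amp = self._tone_amplitude(out.hbo[0, core], t[core], 0.1)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_filtered_mean_is_zero(self):
        rng = np.random.default_rng(1)
        series = make_series(rng.standard_normal((4, 2441)), filter_state="raw")
        out = bandpass(series)
        assert np.all(
            np.abs(out.hbo.mean(axis=1)) < 1e-6 * out.hbo.std(axis=1)
        )
        assert out.filter_state == "filtered"

    def test_band_outside_nyquist_rejected(self):
        series = make_series(np.zeros((1, 100)), filter_state="raw")
        with pytest.raises(ValueError, match="fs/2"):
            bandpass(series, low=0.01, high=5.0)
        with pytest.raises(ValueError):
            bandpass(series, low=0.5, high=0.1)


class TestArtifactWindows:
    W = int(np.floor(10 * FS))  # 81 samples per window

    def _series_with_window_sds(self, sds):
        """Signal whose per-window sample SDs are exactly the given values."""
        base = np.sin(2 * np.pi * np.arange(self.W) / self.W)
        base = (base - base.mean()) / base.std(ddof=1)
        sig = np.concatenate([s * base for s in sds])
        return make_series(sig[None, :])

    def test_identical_window_sds_flag_nothing(self):
        series = self._series_with_window_sds([1.0] * 8)
        with pytest.warns(UserWarning, match="zero MAD"):
            table = detect_artifact_windows(series)
        assert table.is_outlier.sum() == 0

    def test_single_inflated_window_flagged(self):
        """30 near-unit-SD windows + one scaled x10: exactly that one flagged.

        The expected mask is recomputed by brute force from the realized
        window SDs with an independent median/MAD computation.
        """
        sds = np.linspace(0.9, 1.1, 31)
        sds[12] = 10.0
        series = self._series_with_window_sds(sds)
        table = detect_artifact_windows(series)
        sds = window_sds(series.hbo, self.W)[0]
        med = np.median(sds)
        mad = np.median(np.abs(sds - med))
        expected = np.abs(sds - med) > 4.5 * mad
        assert np.array_equal(table.is_outlier[0], expected)
        assert np.flatnonzero(table.is_outlier[0]).tolist() == [12]

    def test_boundary_exactly_at_threshold_not_flagged(self):
        """An SD sitting exactly at median + 4.5*MAD survives (strict >)."""
        sds = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 13.5]])
        # median 4.5, raw MAD 2.0 -> threshold distance 9.0; |13.5-4.5| == 9.0
        mask, med, mad = mad_outlier_mask(sds)
        assert med[0] == 4.5 and mad[0] == 2.0
        assert not mask[0, -1]
        mask_above, _, _ = mad_outlier_mask(np.array([[1, 2, 3, 4, 5, 6, 7, 13.6]]))
        assert mask_above[0, -1]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 12 * self.W))
        x[0, : self.W] *= 20
        t1 = detect_artifact_windows(make_series(x))
        t2 = detect_artifact_windows(make_series(3.0 * x))
        assert np.allclose(t2.sds, 3.0 * t1.sds)
        assert np.allclose(t2.mads, 3.0 * t1.mads)
        assert np.array_equal(t1.is_outlier, t2.is_outlier)

    def test_mask_idempotent(self):
        rng = np.random.default_rng(4)
        series = make_series(rng.standard_normal((3, 10 * self.W)))
        t1 = detect_artifact_windows(series)
        t2 = detect_artifact_windows(series)
        assert np.array_equal(t1.is_outlier, t2.is_outlier)

    def test_too_few_windows_rejected(self):
        series = make_series(np.zeros((1, 2 * self.W)))
        with pytest.raises(ValueError, match="at least 3"):
            detect_artifact_windows(series)

    def test_trailing_partial_window_discarded(self):
        rng = np.random.default_rng(5)
        series = make_series(rng.standard_normal((1, 5 * self.W + 40)))
        table = detect_artifact_windows(series)
        assert table.n_windows == 5
        assert table.window_samples == self.W
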