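"""Raw-signal preprocessing: MBLL conversion, band-pass filtering, artifact windows.

The stages follow standard continuous-wave fNIRS practice:

1. Optical-density changes at the two wavelengths are converted to
   oxy-/deoxyhemoglobin concentration changes by inverting the modified
   Beer-Lambert law (MBLL) pointwise:

       dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * L * DPF(lambda)

   with L the source-detector separation and DPF the differential
   pathlength factor.
2. Concentration series are band-pass filtered to 0.01-0.5 Hz with a
   zero-phase (forward-backward) Butterworth filter, removing cardiac
   pulsation (~1 Hz) and slow baseline drift.
3. Motion artifacts are screened per channel by the SD of the filtered
   oxyhemoglobin signal in nonoverlapping 10-s windows: a window is an
   outlier when its SD deviates from the median of the channel's window
   SDs by strictly more than 4.5 times their median absolute deviation.
   Flagged windows are only masked; the time series is never repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import (
    SEPARATION_CM,
    WAVELENGTHS,
    ChannelLayout,
    HemoSeries,
    RawRecording,
    WindowTable,
)

__all__ = [
    "MBLLCoefficients",
    "mbll_convert",
    "forward_mbll",
    "bandpass",
    "mad_outlier_mask",
    "detect_artifact_windows",
    "RawRecording",
    "HemoSeries",
    "WindowTable",
]

# Molar extinction coefficients in mM^-1 cm^-1 at (780, 850) nm, rows are
# wavelengths, columns are (HbO, HbR). Literature-tabulated values; the
# device vendor's exact constants can be substituted via configuration.
DEFAULT_EXTINCTION = np.array(
    [
        [0.735, 1.030],  # 780 nm
        [1.058, 0.691],  # 850 nm
    ]
)

DEFAULT_DPF = (6.0, 6.0)


class ConfigurationError(ValueError):
    """Raised for invalid coefficient/filter configuration."""


@dataclass(frozen=True)
class MBLLCoefficients:
    """Coefficients of the modified Beer-Lambert law.

    Parameters
    ----------
    extinction : ndarray, shape (2, 2)
        Molar extinction coefficients in mM^-1 cm^-1; rows index the
        wavelengths, columns the chromophores (HbO, HbR).
    dpf : tuple of float
        Differential pathlength factor per wavelength (dimensionless).
    separation : float
        Source-detector separation in cm.
    wavelengths : tuple of float
        Wavelengths in nm, matching the rows of ``extinction``.
    """

    extinction: np.ndarray
    dpf: tuple[float, float] = DEFAULT_DPF
    separation: float = SEPARATION_CM
    wavelengths: tuple[float, float] = WAVELENGTHS

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        object.__setattr__(self, "extinction", ext)
        if ext.shape != (2, 2):
            raise ConfigurationError("extinction matrix must be 2x2")
        if np.linalg.cond(ext) >= 1e6:
            raise ConfigurationError("extinction matrix is singular or ill-conditioned")
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("dpf must be positive")
        if self.separation <= 0:
            raise ConfigurationError("separation must be positive")

    @classmethod
    def default(cls) -> "MBLLCoefficients":
        return cls(extinction=DEFAULT_EXTINCTION.copy())

    @property
    def pathlengths(self) -> np.ndarray:
        """Effective pathlength L * DPF(lambda) per wavelength, in cm."""
        return self.separation * np.asarray(self.dpf, dtype=float)


def forward_mbll(
    hbo: np.ndarray, hbr: np.ndarray, coef: MBLLCoefficients | None = None
) -> np.ndarray:
    """Map concentration changes to optical-density changes (forward MBLL).

    Parameters
    ----------
    hbo, hbr : ndarray, shape (n_channels, n_samples)
        Concentration changes in mM.

    Returns
    -------
    ndarray, shape (n_channels, 2, n_samples)
        Optical-density changes at the two wavelengths.
    """
    coef = coef or MBLLCoefficients.default()
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    conc = np.stack([hbo, hbr], axis=1)  # (n_ch, 2, n_t)
    scaled_ext = coef.extinction * coef.pathlengths[:, None]  # (2 wl, 2 chromo)
    return np.einsum("wc,nct->nwt", scaled_ext, conc)


def mbll_convert(rec: RawRecording, coef: MBLLCoefficients | None = None) -> HemoSeries:
    """Invert the modified Beer-Lambert law per time point.

    Solves the 2x2 linear system relating the two wavelengths' dOD to
    (dHbO, dHbR) for every channel and sample. The map is linear and
    pointwise, so it preserves temporal order and scales.

    Raises
    ------
    ConfigurationError
        If the extinction matrix is singular.
    ValueError
        If the recording's wavelengths do not match the coefficients'.
    """
    coef = coef or MBLLCoefficients.default()
    if tuple(rec.wavelengths) != tuple(coef.wavelengths):
        raise ValueError(
            f"wavelength mismatch: recording {rec.wavelengths} vs coefficients {coef.wavelengths}"
        )
    scaled_ext = coef.extinction * coef.pathlengths[:, None]
    inv = np.linalg.inv(scaled_ext)
    conc = np.einsum("cw,nwt->nct", inv, rec.delta_od)
    return HemoSeries(
        subject_id=rec.subject_id,
        channel_ids=rec.layout.channel_ids.copy(),
        hbo=conc[:, 0, :],
        hbr=conc[:, 1, :],
        fs=rec.fs,
        filter_state="raw",
    )


def bandpass(
    series: HemoSeries,
    low: float = 0.01,
    high: float = 0.5,
    order: int = 3,
) -> HemoSeries:
    """Zero-phase Butterworth band-pass of both hemoglobin series.

    A forward-backward pass of an ``order``-per-pass Butterworth filter
    (applied via second-order sections) gives zero phase shift, so window
    SDs are computed on undistorted waveforms. The residual DC offset left
    by the finite-length filter transient is subtracted so the filtered
    series are exactly mean-free, consistent with DC lying outside the
    passband.

    Raises
    ------
    ValueError
        If the band does not satisfy 0 < low < high < fs/2.
    """
    nyq = series.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=series.fs, output="sos")
    hbo = signal.sosfiltfilt(sos, series.hbo, axis=-1)
    hbr = signal.sosfiltfilt(sos, series.hbr, axis=-1)
    hbo = hbo - hbo.mean(axis=-1, keepdims=True)
    hbr = hbr - hbr.mean(axis=-1, keepdims=True)
    return HemoSeries(
        subject_id=series.subject_id,
        channel_ids=series.channel_ids.copy(),
        hbo=hbo,
        hbr=hbr,
        fs=series.fs,
        filter_state="filtered",
    )


def window_sds(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Sample SDs of ``x`` in adjacent nonoverlapping windows.

    ``x`` has shape (n_channels, n_samples); the trailing partial window
    is discarded. Returns shape (n_channels, n_windows).
    """
    n_ch, n_t = x.shape
    n_w = n_t // window_samples
    if n_w == 0:
        return np.empty((n_ch, 0))
    trimmed = x[:, : n_w * window_samples].reshape(n_ch, n_w, window_samples)
    return trimmed.std(axis=-1, ddof=1)


def mad_outlier_mask(
    sds: np.ndarray,
    threshold_multiplier: float = 4.5,
    scaled_mad: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the median/MAD outlier rule to per-channel window SDs.

    A window is flagged when |sd - median| > threshold * MAD, strict
    inequality, per channel (rows). The MAD is raw by default; channels
    with zero MAD flag nothing (degenerate, warned).

    Returns (is_outlier, medians, mads).
    """
    sds = np.atleast_2d(np.asarray(sds, dtype=float))
    medians = np.median(sds, axis=1)
    mads = np.median(np.abs(sds - medians[:, None]), axis=1)
    if scaled_mad:
        mads = mads * 1.4826
    is_outlier = np.abs(sds - medians[:, None]) > threshold_multiplier * mads[:, None]
    degenerate = mads == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) have zero MAD of window SDs; "
            "no windows excluded there",
            stacklevel=2,
        )
        is_outlier[degenerate, :] = False
    return is_outlier, medians, mads


def detect_artifact_windows(
    series: HemoSeries,
    window_s: float = 10.0,
    threshold_multiplier: float = 4.5,
    source: str = "hbo",
    scaled_mad: bool = False,
) -> WindowTable:
    """Flag motion-artifact windows by the windowed-SD / MAD rule.

    Per channel, the SD of the chosen signal is computed in adjacent
    nonoverlapping windows of ``window_s`` seconds (trailing partial
    window discarded). A window is an outlier when

        |sd - median(sds)| > threshold_multiplier * MAD(sds)

    with strict inequality. The MAD is the raw median absolute deviation
    by default (no 1.4826 normal-consistency factor); set
    ``scaled_mad=True`` for the consistency-scaled variant. A channel
    whose window SDs have zero MAD yields no exclusions (degenerate case,
    warned).

    Parameters
    ----------
    series : HemoSeries
        Band-pass filtered concentration series.
    source : {"hbo", "hbr"}
        Which signal drives the detection (oxyhemoglobin by default).

    Returns
    -------
    WindowTable
        Window SDs, per-channel median/MAD, and the outlier mask. The
        underlying time series is left untouched.

    Raises
    ------
    ValueError
        If fewer than 3 complete windows fit in the recording.
    """
    if series.filter_state != "filtered":
        warnings.warn("artifact detection expects a band-pass filtered series", stacklevel=2)
    if source not in ("hbo", "hbr"):
        raise ValueError("source must be 'hbo' or 'hbr'")
    x = series.hbo if source == "hbo" else series.hbr
    window_samples = int(np.floor(window_s * series.fs))
    n_w = x.shape[1] // window_samples
    if n_w < 3:
        raise ValueError(
            f"need at least 3 complete {window_s}-s windows, got {n_w} "
            f"({x.shape[1]} samples at {series.fs} Hz)"
        )
    sds = window_sds(x, window_samples)
    is_outlier, medians, mads = mad_outlier_mask(
        sds, threshold_multiplier, scaled_mad=scaled_mad
    )
    return WindowTable(
        channel_ids=series.channel_ids.copy(),
        window_s=window_s,
        window_samples=window_samples,
        sds=sds,
        medians=medians,
        mads=mads,
        is_outlier=is_outlier,
        threshold_multiplier=threshold_multiplier,
    )
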