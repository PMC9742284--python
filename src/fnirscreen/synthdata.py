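"""Synthetic resting-state prefrontal fNIRS cohorts.

The study data this pipeline targets (5-min resting recordings from 21
Alzheimer's patients and 18 controls on a 48-channel forehead probe) are
not publicly deposited, so this module generates cohorts with the
statistical structure the analysis assumes:

* a latent oxyhemoglobin signal per channel dominated by a low-frequency
  (0.02-0.2 Hz) resting oscillation, plus Mayer waves (~0.1 Hz),
  respiration (~0.25 Hz) and slow drift;
* a group effect modeled as a multiplicative amplitude ratio
  (``effect_size`` = control over patient) on the low-frequency band in a
  configurable subset of "informative" channels — patients' resting
  prefrontal amplitude is reduced relative to controls;
* cardiac pulsation (~1.1 Hz) added at the optical level;
* sporadic motion artifacts injected as brief (1-3 s) square/spike
  excursions of 8-20x the background optical SD at Poisson event times;
* conversion of the latent concentrations to dual-wavelength
  optical-density changes through the same forward MBLL equations the
  preprocessing stage inverts, so the generator and the analysis share
  one set of coefficients.

With ``effect_size = 1`` the two groups are exchangeable in
distribution; the amplitude ratio in informative channels equals
``effect_size`` in expectation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .containers import (
    N_CHANNELS,
    SEPARATION_CM,
    ChannelLayout,
    RawRecording,
    SubjectMeta,
)
from .preprocess import MBLLCoefficients, forward_mbll

__all__ = [
    "SynthParams",
    "generate_layout",
    "simulate_subject",
    "generate_cohort",
    "ChannelLayout",
    "SubjectMeta",
]

# Deterministic physiological frequencies (Hz) of the forward model.
MAYER_HZ = 0.1
RESP_HZ = 0.25
CARDIAC_HZ_RANGE = (1.05, 1.2)
LOWFREQ_BAND = (0.02, 0.2)

#: Default informative channels: a 2x2 block in the upper-left (left
#: dorsolateral) region of the 6x8 grid; four channels, matching the
#: subset size at which classification peaks.
DEFAULT_INFORMATIVE = (2, 3, 10, 11)

# Neuropsychological score distributions used for plausible patient
# fixtures: (mean, SD, lower clip, upper clip). SDs are reconstructed
# from published cohort standard errors at n = 17 tested patients; these
# are plausibility fixtures, not a claim of distributional fidelity.
_PATIENT_SCORES = {
    "MMSE": (20.20, 1.14 * np.sqrt(17), 0.0, 30.0),
    "BNT": (19.00, 1.42 * np.sqrt(17), 0.0, 30.0),
    "VerbalMemoryTotalRecall": (8.65, 1.19 * np.sqrt(17), 0.0, 15.0),
}
_CONTROL_SCORES = {"MMSE": (27.5, 1.5, 24.0, 30.0)}

#: Fraction of patients without neuropsychological scores (4 of 21 in the
#: emulated cohort were not testable).
_UNTESTED_FRACTION = 4 / 21


class SynthParamError(ValueError):
    """Raised when a synthesis parameter is invalid; names the field."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_patients, n_controls : int
        Cohort sizes (defaults 21 / 18).
    fs : float
        Sampling rate in Hz (default 8.138).
    duration : float
        Recording length in seconds (default 300, the 5-min resting state).
    effect_size : float
        Control-over-patient low-frequency HbO amplitude ratio in the
        informative channels. 1 makes the groups exchangeable; 0
        degenerates the low-frequency signal in controls' informative
        channels.
    informative_channels : tuple of int
        Channel ids carrying the group effect.
    lf_amplitude : float
        SD (mM) of the 0.02-0.2 Hz oxyhemoglobin oscillation at the
        baseline (patient) level.
    mayer_amplitude, resp_amplitude, drift_amplitude : float
        Amplitudes (mM) of the Mayer-wave, respiratory and drift
        components of the latent HbO signal.
    cardiac_amplitude : float
        Amplitude (optical density units) of the cardiac pulsation added
        at the optical level.
    hbr_ratio : float
        Latent HbR as a fraction of HbO (negative: anticorrelated).
    subject_sigma, channel_sigma : float
        Log-SDs of the lognormal amplitude variability shared across a
        subject's channels and specific to each channel, respectively.
    artifact_rate : float
        Motion-artifact events per minute (Poisson).
    seed : int
        RNG seed; the whole cohort is reproducible from it.
    """

    n_patients: int = 21
    n_controls: int = 18
    fs: float = 8.138
    duration: float = 300.0
    effect_size: float = 2.0
    informative_channels: tuple[int, ...] = DEFAULT_INFORMATIVE
    lf_amplitude: float = 1.0e-3
    mayer_amplitude: float = 4.0e-4
    resp_amplitude: float = 3.0e-4
    drift_amplitude: float = 1.0e-3
    cardiac_amplitude: float = 2.0e-3
    hbr_ratio: float = -0.4
    subject_sigma: float = 0.25
    channel_sigma: float = 0.45
    artifact_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_controls"):
            if getattr(self, name) < 0:
                raise SynthParamError(f"{name} must be non-negative")
        if self.fs <= 0:
            raise SynthParamError("fs must be positive")
        if self.duration <= 0:
            raise SynthParamError("duration must be positive")
        if self.effect_size < 0:
            raise SynthParamError("effect_size must be >= 0")
        for name in (
            "lf_amplitude",
            "mayer_amplitude",
            "resp_amplitude",
            "drift_amplitude",
            "cardiac_amplitude",
        ):
            if getattr(self, name) < 0:
                raise SynthParamError(f"{name} must be >= 0")
        if self.artifact_rate < 0:
            raise SynthParamError("artifact_rate must be >= 0")
        if self.subject_sigma < 0 or self.channel_sigma < 0:
            raise SynthParamError("subject_sigma and channel_sigma must be >= 0")
        if self.fs <= 2 * CARDIAC_HZ_RANGE[1]:
            raise SynthParamError(
                f"fs must exceed twice the highest simulated frequency "
                f"({CARDIAC_HZ_RANGE[1]} Hz)"
            )
        bad = [c for c in self.informative_channels if not (1 <= c <= N_CHANNELS)]
        if bad:
            raise SynthParamError(f"informative_channels out of range 1..{N_CHANNELS}: {bad}")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration * self.fs))


def generate_layout(seed: int = 0) -> ChannelLayout:
    """Fixed 6-row x 8-column forehead grid of the 48 deep channels.

    The probe's true coordinates are proprietary; this arbitrary-but-fixed
    grid (2.0 cm column pitch, 1.5 cm row pitch, small seeded jitter well
    below the pitch) keeps topographic maps reproducible. Channel ids run
    row-major from the top-left; each channel is assigned its own
    synthetic source/detector pair at +-separation/2 along x.
    """
    rng = np.random.default_rng(seed)
    rows, cols = 6, 8
    ids = np.arange(1, rows * cols + 1)
    r, c = np.divmod(ids - 1, cols)
    x = c * 2.0
    y = (rows - 1 - r) * 1.5
    jitter = rng.uniform(-0.1, 0.1, size=(rows * cols, 2))
    positions = np.column_stack([x, y]) + jitter
    return ChannelLayout(
        channel_ids=ids,
        source_ids=ids,
        detector_ids=ids,
        positions=positions,
        separation=SEPARATION_CM,
    )


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (zero-phase Butterworth).

    Filters along the last axis and normalizes each series to zero mean
    and unit sample SD, so amplitude factors applied afterwards set the
    realized SD exactly.
    """
    white = rng.standard_normal(shape)
    sos = sp_signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, white, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    return np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)


def _subject_rng(params: SynthParams, subject_id: str) -> np.random.Generator:
    """Stable per-subject generator derived from the seed and subject id."""
    tag = zlib.crc32(subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence([params.seed, tag]))


def simulate_subject(
    meta: SubjectMeta,
    layout: ChannelLayout,
    params: SynthParams,
    coef: MBLLCoefficients | None = None,
    rng: np.random.Generator | None = None,
    return_latent: bool = False,
) -> RawRecording | tuple[RawRecording, np.ndarray, np.ndarray]:
    """Forward-model one subject's dual-wavelength recording.

    Latent per-channel (dHbO, dHbR) concentration series are built from
    the components described in the module docstring, converted to
    optical-density changes by the forward MBLL, and then cardiac
    pulsation and motion transients are added at the optical level.

    With ``return_latent=True`` the latent (hbo, hbr) arrays are returned
    alongside the recording, which lets the inverse MBLL be checked
    against the ground truth.

    Raises
    ------
    SynthParamError
        If ``params`` is invalid (the error names the offending field).
    """
    params.validate()
    coef = coef or MBLLCoefficients.default()
    if rng is None:
        rng = _subject_rng(params, meta.subject_id)
    n = params.n_samples
    t = np.arange(n) / params.fs
    n_ch = layout.n_channels

    subj_factor = float(np.exp(params.subject_sigma * rng.standard_normal()))
    ch_factors = np.exp(params.channel_sigma * rng.standard_normal(n_ch))
    informative = np.isin(layout.channel_ids, params.informative_channels)

    amp = params.lf_amplitude * subj_factor * ch_factors
    if meta.group == "control":
        amp = np.where(informative, amp * params.effect_size, amp)

    hbo = np.zeros((n_ch, n))
    if params.lf_amplitude > 0:
        hbo = amp[:, None] * _bandlimited_noise(rng, (n_ch, n), params.fs, LOWFREQ_BAND)
    if params.mayer_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        freq = MAYER_HZ * rng.uniform(0.9, 1.1)
        hbo += params.mayer_amplitude * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if params.resp_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        freq = RESP_HZ * rng.uniform(0.85, 1.15)
        hbo += params.resp_amplitude * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if params.drift_amplitude > 0:
        slopes = rng.uniform(-1.0, 1.0, n_ch)
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        ramp = t / t[-1] - 0.5 if n > 1 else t * 0.0
        hbo += params.drift_amplitude * (
            slopes[:, None] * ramp[None, :]
            + 0.5 * np.sin(2 * np.pi * 0.003 * t[None, :] + phases[:, None])
        )
    hbr = params.hbr_ratio * hbo

    delta_od = forward_mbll(hbo, hbr, coef)

    if params.cardiac_amplitude > 0:
        f_card = rng.uniform(*CARDIAC_HZ_RANGE)
        phase = rng.uniform(0, 2 * np.pi)
        ch_phase = rng.uniform(-0.3, 0.3, n_ch)
        pulse = np.sin(2 * np.pi * f_card * t[None, :] + phase + ch_phase[:, None])
        # slow amplitude modulation, slightly weaker at the longer wavelength
        envelope = 1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t)
        delta_od[:, 0, :] += params.cardiac_amplitude * envelope * pulse
        delta_od[:, 1, :] += 0.8 * params.cardiac_amplitude * envelope * pulse

    if params.artifact_rate > 0:
        _inject_artifacts(delta_od, params, rng)

    rec = RawRecording(
        subject_id=meta.subject_id,
        layout=layout,
        delta_od=delta_od,
        fs=params.fs,
        wavelengths=coef.wavelengths,
    )
    if return_latent:
        return rec, hbo, hbr
    return rec


def _inject_artifacts(delta_od: np.ndarray, params: SynthParams, rng: np.random.Generator) -> None:
    """Add square/spike motion transients in place, at Poisson event times.

    Each event spans 1-3 s, hits all channels with random per-channel
    scaling, and has amplitude 8-20x the channel's background optical SD
    — large enough that the windowed-SD/MAD rule must catch it.
    """
    n_ch, _, n = delta_od.shape
    fs = params.fs
    n_events = rng.poisson(params.artifact_rate * params.duration / 60.0)
    if n_events == 0:
        return
    bg_sd = delta_od.std(axis=2, ddof=1)  # (n_ch, 2)
    bg_sd = np.where(bg_sd > 0, bg_sd, 1e-4)
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - 1))
        dur = int(rng.uniform(1.0, 3.0) * fs)
        stop = min(n, start + max(1, dur))
        width = stop - start
        scale = rng.uniform(8.0, 20.0)
        sign = rng.choice([-1.0, 1.0])
        ch_scale = rng.uniform(0.5, 1.5, n_ch)
        if rng.random() < 0.5:  # square pulse
            shape = np.ones(width)
        else:  # spike with exponential decay
            shape = np.exp(-np.arange(width) / max(1.0, 0.2 * width))
        bump = sign * scale * shape[None, :]
        for w in range(2):
            delta_od[:, w, start:stop] += bump * (ch_scale * bg_sd[:, w])[:, None]


def _draw_scores(rng: np.random.Generator, table: dict) -> dict[str, float]:
    scores = {}
    for name, (mean, sd, lo, hi) in table.items():
        val = float(np.clip(np.round(rng.normal(mean, sd)), lo, hi))
        scores[name] = val
    return scores


def _generate_metadata(params: SynthParams, rng: np.random.Generator) -> list[SubjectMeta]:
    """Draw subject metadata; patient scores are redrawn until every test
    admits a well-defined median split (not all equal, both sides of the
    strict-greater rule nonempty)."""
    metas: list[SubjectMeta] = []
    n_untested = int(round(_UNTESTED_FRACTION * params.n_patients))
    untested = set(
        rng.choice(params.n_patients, size=n_untested, replace=False).tolist()
        if n_untested > 0
        else []
    )
    for i in range(params.n_patients):
        sid = f"P{i + 1:02d}"
        if i in untested:
            metas.append(SubjectMeta(subject_id=sid, group="patient"))
            continue
        scores = _draw_scores(rng, _PATIENT_SCORES)
        metas.append(SubjectMeta(subject_id=sid, group="patient", test_scores=scores))
    # global retry: ensure each test's patient scores are splittable
    tested = [m for m in metas if m.test_scores]
    if len(tested) >= 4:
        for name in _PATIENT_SCORES:
            for _attempt in range(50):
                vals = np.array([m.test_scores[name] for m in metas if m.test_scores])
                med = np.median(vals)
                if np.any(vals > med) and np.any(vals <= med) and not np.all(vals == vals[0]):
                    break
                # redraw this test's scores for all tested patients
                for j, m in enumerate(metas):
                    if m.test_scores:
                        new = dict(m.test_scores)
                        new[name] = _draw_scores(rng, {name: _PATIENT_SCORES[name]})[name]
                        metas[j] = replace(m, test_scores=new)
    for i in range(params.n_controls):
        sid = f"C{i + 1:02d}"
        scores = _draw_scores(rng, _CONTROL_SCORES)
        metas.append(SubjectMeta(subject_id=sid, group="control", test_scores=scores))
    return metas


def generate_cohort(
    params: SynthParams | None = None,
    layout: ChannelLayout | None = None,
    coef: MBLLCoefficients | None = None,
) -> tuple[list[RawRecording], list[SubjectMeta]]:
    """Generate a full synthetic cohort: recordings plus metadata.

    Fully reproducible from ``params.seed``: the seed is split into
    independent per-subject streams, so simulating any one subject in
    isolation yields the same recording as inside the cohort.

    Raises
    ------
    SynthParamError
        If parameters are invalid or the cohort has fewer than 5 subjects.
    """
    params = params or SynthParams()
    params.validate()
    total = params.n_patients + params.n_controls
    if total < 5:
        raise SynthParamError("cohort must have at least 5 subjects")
    if total < 10:
        warnings.warn(
            f"cohort of {total} subjects is small; 5-fold cross-validation may be infeasible",
            stacklevel=2,
        )
    layout = layout or generate_layout(params.seed)
    meta_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    metas = _generate_metadata(params, meta_rng)
    recordings = [simulate_subject(m, layout, params, coef=coef) for m in metas]
    return recordings, metas
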