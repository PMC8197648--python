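"""Speech-envelope derived tACS current waveforms.

The stimulation waveform is built from an acoustic signal in five steps:

1. envelope extraction — magnitude of the analytic signal of the audio;
2. theta bandpass — zero-phase (forward-backward) Butterworth IIR filter,
   4-8 Hz, order 6;
3. extrema equalization — rescaling so that every interior local maximum
   sits at +1 and every interior local minimum at -1;
4. phase shift — rotation of the analytic signal by an arbitrary angle
   (180 deg is exact pointwise negation);
5. current scaling — peak-normalized scaling to the calibrated maximum
   current in mA.

A sham stimulus (short ramped pulse at sentence onset) is generated
separately.  All operations are deterministic: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.io import wavfile

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    UndefinedCorrelationError,
)

THETA_BAND = (4.0, 8.0)  # Hz
DEFAULT_AUDIO_RATE = 44_100  # Hz
DEFAULT_MAX_CURRENT_MA = 0.67  # cohort-mean skin-sensation calibration


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_finite_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError(f"{name}: expected a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name}: contains non-finite samples")
    return arr


@dataclass(frozen=True)
class AudioSignal:
    """Mono audio, arbitrary amplitude units."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_finite_array(self.samples, "audio"))
        if self.rate <= 0:
            raise InvalidInputError("audio rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class EnvelopeSignal:
    """Non-negative slow amplitude modulation of an audio signal."""

    values: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_finite_array(self.values, "envelope"))
        if self.rate <= 0:
            raise InvalidInputError("envelope rate must be positive")
        if np.any(self.values < 0):
            raise InvalidInputError("envelope values must be non-negative")


@dataclass(frozen=True)
class ThetaEnvelope:
    """Band-limited, zero-mean version of an envelope."""

    values: np.ndarray
    rate: float
    band: tuple[float, float] = THETA_BAND

    def __post_init__(self):
        object.__setattr__(self, "values", _as_finite_array(self.values, "theta envelope"))


@dataclass(frozen=True)
class NormalizedWaveform:
    """Waveform whose interior extrema are equalized to +/-1."""

    values: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_finite_array(self.values, "waveform"))


@dataclass(frozen=True)
class StimulusWaveform:
    """Current waveform in mA, tagged with its provenance."""

    values: np.ndarray
    rate: float
    phase_deg: float
    source: str  # target | distractor | sham
    max_current: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_finite_array(self.values, "stimulus"))
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)
        if self.source not in ("target", "distractor", "sham"):
            raise InvalidInputError(f"unknown stimulation source {self.source!r}")


@dataclass(frozen=True)
class PairCorrelationSummary:
    """Pearson correlations of envelope pairs, with a one-sample t-test of
    the mean correlation against zero."""

    r_values: np.ndarray
    mean_r: float
    sem_r: float
    t: float
    p: float
    truncated: bool = field(default=False)

    @property
    def n_pairs(self) -> int:
        return self.r_values.size


# ---------------------------------------------------------------------------
# envelope extraction and filtering
# ---------------------------------------------------------------------------

def extract_envelope(audio: AudioSignal, decimate: int = 1) -> EnvelopeSignal:
    """Envelope as the magnitude of the analytic signal of the audio.

    The subsequent theta bandpass makes the precise envelope estimator
    non-critical; the analytic magnitude is the standard choice.  An
    optional integer decimation reduces the rate after extraction.
    """
    env = np.abs(sps.hilbert(audio.samples))
    rate = audio.rate
    if decimate > 1:
        env = sps.decimate(env, decimate, zero_phase=True)
        env = np.clip(env, 0.0, None)  # decimation ripple can dip below zero
        rate = audio.rate / decimate
    return EnvelopeSignal(values=env, rate=rate)


def design_theta_bandpass(
    rate: float,
    low: float = THETA_BAND[0],
    high: float = THETA_BAND[1],
    order: int = 6,
) -> np.ndarray:
    """Second-order sections of the Butterworth bandpass used throughout.

    `order` is the order of the bandpass itself (an order-6 bandpass comes
    from an order-3 lowpass prototype).  Applied forward-backward, so the
    effective magnitude response is the square of this design.
    """
    if order <= 0 or order % 2:
        raise ConfigurationError("bandpass order must be even and positive")
    if rate <= 2 * high:
        raise ConfigurationError(
            f"sampling rate {rate} Hz too low for a {high} Hz band edge"
        )
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass_theta(
    env: EnvelopeSignal,
    low: float = THETA_BAND[0],
    high: float = THETA_BAND[1],
    order: int = 6,
) -> ThetaEnvelope:
    """Zero-phase theta bandpass of an envelope (forward-backward IIR)."""
    sos = design_theta_bandpass(env.rate, low, high, order)
    out = sps.sosfiltfilt(sos, env.values)
    return ThetaEnvelope(values=out, rate=env.rate, band=(low, high))


def bandpass_gain(rate: float, freq: float, low: float = THETA_BAND[0],
                  high: float = THETA_BAND[1], order: int = 6) -> float:
    """Magnitude gain of the *zero-phase* filter at `freq` (squared response
    of the single-pass design).  Used as the frequency-response oracle."""
    sos = design_theta_bandpass(rate, low, high, order)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=rate)
    return float(np.abs(h[0]) ** 2)


# ---------------------------------------------------------------------------
# extrema equalization
# ---------------------------------------------------------------------------

def _interior_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (strict neighbours)."""
    maxima, _ = sps.find_peaks(x)
    minima, _ = sps.find_peaks(-x)
    return maxima, minima


def equalize_extrema(theta: ThetaEnvelope, tol: float = 1e-6) -> NormalizedWaveform:
    """Rescale each half-cycle so all interior extrema sit at +/-1.

    The signal is split at its zero crossings; every segment is divided by
    its own peak magnitude.  This keeps zero crossings and extremum
    locations fixed, is continuous (segments meet at zero), and is
    idempotent.
    """
    x = theta.values
    maxima, minima = _interior_extrema(x)
    if maxima.size + minima.size < 2:
        raise DegenerateInputError(
            "extrema equalization needs at least 2 interior extrema"
        )
    out = x.copy()
    # boundaries after sample i whenever the sign flips between i and i+1
    flips = np.flatnonzero(np.signbit(x[:-1]) != np.signbit(x[1:])) + 1
    bounds = np.concatenate(([0], flips, [x.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        peak = np.max(np.abs(x[a:b]))
        if peak > 0:
            out[a:b] = x[a:b] / peak
    return NormalizedWaveform(values=out, rate=theta.rate)


# ---------------------------------------------------------------------------
# phase shift and current scaling
# ---------------------------------------------------------------------------

def _cosd(deg: float) -> float:
    d = deg % 360.0
    exact = {0.0: 1.0, 90.0: 0.0, 180.0: -1.0, 270.0: 0.0}
    if d in exact:
        return exact[d]
    return math.cos(math.radians(d))


def _sind(deg: float) -> float:
    return _cosd(deg - 90.0)


def phase_shift(wave: NormalizedWaveform, degrees: float) -> NormalizedWaveform:
    """Rotate the analytic signal by `degrees` (positive advances phase).

    output = x*cos(theta) - H{x}*sin(theta), with H the Hilbert transform.
    At 0 deg this is the identity; at 180 deg it is exact pointwise
    negation; the instantaneous amplitude |x + iH{x}| is preserved.
    """
    c, s = _cosd(degrees), _sind(degrees)
    if s == 0.0:  # multiples of 180 deg: avoid touching the Hilbert path
        out = wave.values * c
    else:
        h = np.imag(sps.hilbert(wave.values))
        out = wave.values * c - h * s
    return NormalizedWaveform(values=out, rate=wave.rate)


def scale_current(
    wave: NormalizedWaveform,
    max_mA: float = DEFAULT_MAX_CURRENT_MA,
    phase_deg: float = 0.0,
    source: str = "target",
) -> StimulusWaveform:
    """Peak-normalize the waveform to the calibrated maximum current."""
    if max_mA <= 0:
        raise ConfigurationError("maximum current must be positive (mA)")
    peak = np.max(np.abs(wave.values))
    values = wave.values * (max_mA / peak) if peak > 0 else wave.values.copy()
    return StimulusWaveform(
        values=values, rate=wave.rate, phase_deg=phase_deg,
        source=source, max_current=max_mA,
    )


def make_sham(
    rate: float,
    duration_ms: float = 500.0,
    ramp_ms: float = 100.0,
    max_mA: float = DEFAULT_MAX_CURRENT_MA,
    total_ms: float | None = None,
) -> StimulusWaveform:
    """Short ramped current pulse at sentence onset (placebo stimulation).

    Linear on/off ramps of `ramp_ms` enclose a flat plateau; with
    `total_ms` set, the pulse is zero-padded to that total duration.
    """
    if duration_ms < 2 * ramp_ms:
        raise ConfigurationError(
            f"sham duration {duration_ms} ms cannot hold two {ramp_ms} ms ramps"
        )
    n_pulse = int(round(duration_ms * rate / 1000.0))
    n_ramp = int(round(ramp_ms * rate / 1000.0))
    pulse = np.ones(n_pulse)
    if n_ramp > 0:
        ramp = np.arange(1, n_ramp + 1) / n_ramp
        pulse[:n_ramp] = ramp
        pulse[-n_ramp:] = ramp[::-1]
    if total_ms is not None:
        n_total = int(round(total_ms * rate / 1000.0))
        if n_total < n_pulse:
            raise ConfigurationError("total duration shorter than the sham pulse")
        pulse = np.concatenate([pulse, np.zeros(n_total - n_pulse)])
    return StimulusWaveform(
        values=pulse * max_mA, rate=rate, phase_deg=0.0,
        source="sham", max_current=max_mA,
    )


def make_stimulus(
    audio: AudioSignal,
    phase_deg: float = 0.0,
    max_mA: float = DEFAULT_MAX_CURRENT_MA,
    source: str = "target",
) -> StimulusWaveform:
    """Full deterministic chain: audio -> envelope -> theta bandpass ->
    extrema equalization -> phase shift -> current scaling."""
    env = extract_envelope(audio)
    theta = bandpass_theta(env)
    norm = equalize_extrema(theta)
    shifted = phase_shift(norm, phase_deg)
    return scale_current(shifted, max_mA, phase_deg=phase_deg, source=source)


# ---------------------------------------------------------------------------
# envelope-pair correlation
# ---------------------------------------------------------------------------

def pair_pearson_r(env_a: EnvelopeSignal, env_b: EnvelopeSignal) -> tuple[float, bool]:
    """Pearson r of one envelope pair; unequal lengths are truncated to the
    shorter signal (flag returned)."""
    a, b = env_a.values, env_b.values
    truncated = a.size != b.size
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero-variance envelope in correlation")
    return float(stats.pearsonr(a, b).statistic), truncated


def envelope_pair_correlation(
    pairs: Sequence[tuple[EnvelopeSignal, EnvelopeSignal]],
) -> PairCorrelationSummary:
    """Per-pair Pearson r, the mean and SEM across pairs, and a two-tailed
    one-sample t-test of the mean correlation against zero."""
    if len(pairs) == 0:
        raise InvalidInputError("no envelope pairs supplied")
    rs, truncated = [], False
    for env_a, env_b in pairs:
        r, trunc = pair_pearson_r(env_a, env_b)
        rs.append(r)
        truncated |= trunc
    rs = np.asarray(rs)
    mean_r = float(np.mean(rs))
    sem_r = float(stats.sem(rs)) if rs.size > 1 else float("nan")
    if rs.size > 1:
        t, p = stats.ttest_1samp(rs, 0.0)
    else:
        t, p = float("nan"), float("nan")
    return PairCorrelationSummary(
        r_values=rs, mean_r=mean_r, sem_r=sem_r,
        t=float(t), p=float(p), truncated=truncated,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> AudioSignal:
    """Read mono PCM/float WAV; multi-channel input is averaged to mono."""
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(samples=data, rate=float(rate))


def write_stimulus(stim: StimulusWaveform, stem: str | Path) -> dict:
    """Write a stimulus as float WAV + CSV (time_s, current_mA) + JSON
    metadata sidecar; returns the metadata dict."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(stem.with_suffix(".wav"), int(round(stim.rate)),
                  stim.values.astype(np.float32))
    t = np.arange(stim.values.size) / stim.rate
    np.savetxt(
        stem.with_suffix(".csv"),
        np.column_stack([t, stim.values]),
        delimiter=",", header="time_s,current_mA", comments="",
    )
    meta = {
        "source": stim.source,
        "phase_deg": stim.phase_deg,
        "rate_hz": stim.rate,
        "max_current_ma": stim.max_current,
        "band_hz": list(THETA_BAND),
        "n_samples": int(stim.values.size),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return meta
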