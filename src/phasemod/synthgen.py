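"""Synthetic cohort scores and surrogate speech envelopes.

The generator emulates the study design: 18 subjects, comprehension
measured at four stimulation phases (0/90/180/270 deg) for waveforms
derived from the target and the distractor speech envelope, plus a sham
condition; each condition scores 26 sentences x 5 keywords = 130
keywords, presented near the 50% sentence reception threshold.  The
ground truth is a sinusoidal phase modulation of the per-keyword
probability: amplitude 3.0 percentage points peaking at 0 deg for
target-envelope stimulation, 1.6 points peaking at 180 deg for
distractor-envelope stimulation, zero for sham.  Scoring noise is
binomial at the keyword level; subjects get a Gaussian offset of their
overall level (SD 5 points by default).

Surrogate envelopes stand in for the envelopes of spoken sentences: 1/f
pink noise bandpassed to the theta range, rectified and offset to be
non-negative; the two members of a pair come from independent substreams
of a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, InvalidInputError
from .waveform import EnvelopeSignal, THETA_BAND, design_theta_bandpass
from .phase_model import STUDY_PHASES

N_SUBJECTS = 18
N_SENTENCES = 26
KEYWORDS_PER_SENTENCE = 5
N_KEYWORDS = N_SENTENCES * KEYWORDS_PER_SENTENCE  # 130 per condition


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth parameters of a synthetic cohort."""

    n_subjects: int = N_SUBJECTS
    n_keywords: int = N_KEYWORDS
    cs_mean: float = 50.0                 # percent, near-SRT operating point
    a1_true: dict = field(default_factory=lambda: {"target": 3.0,
                                                   "distractor": 1.6,
                                                   "sham": 0.0})
    phi1_true_deg: dict = field(default_factory=lambda: {"target": 0.0,
                                                         "distractor": 180.0,
                                                         "sham": 0.0})
    subject_sd: float = 5.0               # between-subject offset SD (points)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.n_keywords < 1:
            raise ConfigurationError("need at least 1 keyword per condition")
        worst = max(abs(a) for a in self.a1_true.values())
        if not (0 < self.cs_mean < 100):
            raise ConfigurationError("cs_mean must lie in (0, 100) percent")
        if self.cs_mean - worst <= 0 or self.cs_mean + worst >= 100:
            raise ConfigurationError("modulation pushes probabilities out of (0, 1)")


def generate_cohort(params: CohortParams | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Long-form cohort score table with known ground truth.

    Per subject s, source and phase phi, the keyword-correct count is
    n_correct ~ Binomial(n_keywords, p) with
    p = clamp(cs_mean + offset_s + A1_true cos(phi - phi1_true)) / 100.
    Sham has no phase dependence and is emitted with phase_deg = NaN.
    Deterministic for a fixed (params, seed).
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    offsets = rng.normal(0.0, params.subject_sd, size=params.n_subjects)
    rows = []
    for s in range(params.n_subjects):
        base = params.cs_mean + offsets[s]
        for source in ("target", "distractor", "sham"):
            a1 = params.a1_true[source]
            phi1 = np.radians(params.phi1_true_deg[source])
            phases = STUDY_PHASES if source != "sham" else (np.nan,)
            for phase in phases:
                mod = 0.0 if np.isnan(phase) else a1 * np.cos(np.radians(phase) - phi1)
                p = np.clip((base + mod) / 100.0, 1e-9, 1 - 1e-9)
                n_correct = int(rng.binomial(params.n_keywords, p))
                rows.append({
                    "subject_id": f"S{s + 1:02d}",
                    "source": source,
                    "phase_deg": phase,
                    "n_keywords": params.n_keywords,
                    "n_correct": n_correct,
                })
    return pd.DataFrame(rows)


def ground_truth(params: CohortParams | None = None) -> dict:
    """JSON-serializable ground-truth record for recovery testing."""
    params = params or CohortParams()
    return {
        "n_subjects": params.n_subjects,
        "n_keywords": params.n_keywords,
        "cs_mean": params.cs_mean,
        "a1_true": dict(params.a1_true),
        "phi1_true_deg": dict(params.phi1_true_deg),
        "subject_sd": params.subject_sd,
        "seed": params.seed,
    }


def inject_outliers(centered: pd.DataFrame, fraction: float = 0.10,
                    magnitude: float = 30.0, seed: int = 0) -> pd.DataFrame:
    """Displace a fraction of centered scores by +/-`magnitude` points.

    Gross-outlier contamination of the regression response (delta_cs),
    used to exercise the robust-vs-standard comparison.  Signs are random;
    rows are chosen without replacement.
    """
    if not (0 < fraction < 1):
        raise ConfigurationError("outlier fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = centered.copy()
    n_out = max(1, int(round(fraction * len(out))))
    rows = rng.choice(len(out), size=n_out, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_out)
    out.iloc[rows, out.columns.get_loc("delta_cs")] += signs * magnitude
    return out


# ---------------------------------------------------------------------------
# surrogate envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateEnvelopeParams:
    duration_s: float = 4.0
    rate: float = 256.0
    mod_band: tuple[float, float] = THETA_BAND
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 2:
            raise ConfigurationError("surrogate envelopes need >= 2 s duration")
        if self.rate < 64:
            raise ConfigurationError("surrogate envelope rate must be >= 64 Hz")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximately 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    return np.fft.irfft(spec * shaping, n=n)


def _one_envelope(params: SurrogateEnvelopeParams,
                  rng: np.random.Generator) -> EnvelopeSignal:
    n = int(round(params.duration_s * params.rate))
    noise = _pink_noise(n, rng)
    sos = design_theta_bandpass(params.rate, *params.mod_band)
    theta = sps.sosfiltfilt(sos, noise)
    theta = theta / np.max(np.abs(theta))
    # rectified-plus-offset: non-negative, modulation power stays in band
    env = theta - np.min(theta)
    return EnvelopeSignal(values=env, rate=params.rate)


def generate_envelope_pair(
    params: SurrogateEnvelopeParams | None = None,
    same_signal: bool = False,
    member_seeds: tuple[int, int] | None = None,
) -> tuple[EnvelopeSignal, EnvelopeSignal]:
    """A pair of statistically independent surrogate envelopes.

    By default the two members are drawn from distinct substreams spawned
    from `params.seed`, so they are independent by construction.  Explicit
    `member_seeds` must differ — requesting the same seed for both members
    would silently break the independence contract and is rejected; use
    `same_signal=True` for the perfectly correlated control (the identical
    envelope twice, r = 1).
    """
    params = params or SurrogateEnvelopeParams()
    if member_seeds is not None:
        if member_seeds[0] == member_seeds[1] and not same_signal:
            raise ConfigurationError(
                "identical member seeds would produce a dependent pair; "
                "use same_signal=True if that is intended"
            )
        child_a = np.random.SeedSequence(member_seeds[0])
        child_b = np.random.SeedSequence(member_seeds[1])
    else:
        child_a, child_b = np.random.SeedSequence(params.seed).spawn(2)
    env_a = _one_envelope(params, np.random.default_rng(child_a))
    if same_signal:
        return env_a, env_a
    env_b = _one_envelope(params, np.random.default_rng(child_b))
    return env_a, env_b


def generate_envelope_pairs(
    n_pairs: int,
    params: SurrogateEnvelopeParams | None = None,
) -> list[tuple[EnvelopeSignal, EnvelopeSignal]]:
    """`n_pairs` independent envelope pairs from one master seed."""
    if n_pairs < 1:
        raise InvalidInputError("need at least one pair")
    params = params or SurrogateEnvelopeParams()
    master = np.random.SeedSequence(params.seed)
    pairs = []
    for child in master.spawn(n_pairs):
        sub_a, sub_b = child.spawn(2)
        env_a = _one_envelope(params, np.random.default_rng(sub_a))
        env_b = _one_envelope(params, np.random.default_rng(sub_b))
        pairs.append((env_a, env_b))
    return pairs


def modulation_band_power_fraction(env: EnvelopeSignal,
                                   band: tuple[float, float] = THETA_BAND) -> float:
    """Fraction of the envelope's (mean-removed) spectral power inside
    `band`, from a periodogram."""
    x = env.values - np.mean(env.values)
    freqs, pxx = sps.periodogram(x, fs=env.rate)
    total = np.sum(pxx)
    if total == 0:
        return 0.0
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(pxx[in_band]) / total)
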