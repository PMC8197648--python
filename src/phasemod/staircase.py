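"""Adaptive 1-up/1-down speech-reception-threshold (SRT) staircase.

A virtual listener repeats sentences of five keywords at a given SNR; the
number of correctly repeated keywords is binomial with a logistic
psychometric function of SNR.  The adaptive track starts at a random SNR
between -3 and 0 dB; if at most two of five keywords are correct the SNR
is raised by 1 dB for the next trial, otherwise lowered by 1 dB.  The
track stops after seven reversals or 17 trials.  Four such runs give the
SRT estimate: by default the mean, over the last three runs, of each
run's final three presented SNR values.

For a symmetric psychometric function with no guess/lapse, the 1-up/1-down
rule on the "more than 2 of 5 keywords" criterion converges to the SNR
where P(>=3 correct) = 0.5; at the keyword level this is exactly the 50%
point, because Binomial(5, 1/2) puts probability 1/2 on {3, 4, 5}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidInputError

N_KEYWORDS = 5
UP_RULE_MAX_CORRECT = 2    # <= 2 of 5 correct -> harder? no: SNR goes UP
STEP_DB = 1.0
MAX_REVERSALS = 7
MAX_TRIALS = 17
N_RUNS = 4
START_SNR_RANGE = (-3.0, 0.0)


@dataclass(frozen=True)
class ListenerModel:
    """Logistic virtual listener.

    `srt_true` is the SNR (dB) of 50% keyword accuracy with no guessing
    or lapsing; `slope` is the maximum slope of the psychometric function
    in probability per dB; `guess` and `lapse` clamp the asymptotes.
    """

    srt_true: float
    slope: float = 0.2
    guess: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ConfigurationError("psychometric slope must be positive")
        if not (0 <= self.guess <= 0.1 and 0 <= self.lapse <= 0.1):
            raise ConfigurationError("guess/lapse rates must lie in [0, 0.1]")

    def p_correct(self, snr_db: float) -> float:
        """Per-keyword probability of a correct response at `snr_db`."""
        span = 1.0 - self.guess - self.lapse
        k = 4.0 * self.slope / span  # logistic rate giving max slope `slope`
        core = 1.0 / (1.0 + np.exp(-k * (snr_db - self.srt_true)))
        return float(self.guess + span * core)


@dataclass(frozen=True)
class StaircaseRun:
    snr_track: np.ndarray      # presented SNR per trial (dB)
    n_correct: np.ndarray      # keywords correct per trial
    reversals: np.ndarray      # trial indices where direction reversed
    stopped_by: str            # "reversals" | "max_trials"

    @property
    def n_trials(self) -> int:
        return self.snr_track.size


@dataclass(frozen=True)
class SrtEstimate:
    srt_db: float
    runs: tuple[StaircaseRun, ...]
    estimator: str             # "mean_last3_snr" | "final_snr"


def simulate_trial(listener: ListenerModel, snr_db: float,
                   rng: np.random.Generator,
                   n_keywords: int = N_KEYWORDS) -> int:
    """Number of correctly repeated keywords in one sentence trial."""
    if n_keywords < 1:
        raise InvalidInputError("need at least one keyword")
    return int(rng.binomial(n_keywords, listener.p_correct(snr_db)))


def find_reversals(snr_track: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Trial indices at which the step direction changed sign."""
    directions = np.asarray(directions)
    flips = np.flatnonzero(directions[1:] != directions[:-1]) + 1
    return flips


def run_staircase(
    listener: ListenerModel,
    rng: np.random.Generator,
    start_snr: float | None = None,
    integer_start: bool = False,
) -> StaircaseRun:
    """One adaptive 1-up/1-down track (7 reversals or 17 trials)."""
    if start_snr is None:
        if integer_start:
            start_snr = float(rng.integers(int(START_SNR_RANGE[0]),
                                           int(START_SNR_RANGE[1]) + 1))
        else:
            start_snr = float(rng.uniform(*START_SNR_RANGE))
    snr = start_snr
    track, correct, dirs = [], [], []
    n_reversals = 0
    stopped_by = "max_trials"
    for _ in range(MAX_TRIALS):
        nc = simulate_trial(listener, snr, rng)
        track.append(snr)
        correct.append(nc)
        step = STEP_DB if nc <= UP_RULE_MAX_CORRECT else -STEP_DB
        dirs.append(step)
        if len(dirs) > 1 and dirs[-1] != dirs[-2]:
            n_reversals += 1
            if n_reversals >= MAX_REVERSALS:
                stopped_by = "reversals"
                snr += step
                break
        snr += step
    track = np.asarray(track)
    dirs = np.asarray(dirs)
    return StaircaseRun(
        snr_track=track, n_correct=np.asarray(correct, dtype=int),
        reversals=find_reversals(track, dirs), stopped_by=stopped_by,
    )


def estimate_srt(runs, estimator: str = "mean_last3_snr") -> SrtEstimate:
    """SRT from four runs: average over the last three runs.

    `estimator="mean_last3_snr"` (default) takes, within each of the last
    three runs, the mean of that run's final three presented SNR values;
    `estimator="final_snr"` takes each run's final presented SNR instead.
    """
    runs = tuple(runs)
    if len(runs) != N_RUNS:
        raise InvalidInputError(f"SRT estimation needs exactly {N_RUNS} runs")
    last3 = runs[-3:]
    if estimator == "mean_last3_snr":
        per_run = [float(np.mean(r.snr_track[-3:])) for r in last3]
    elif estimator == "final_snr":
        per_run = [float(r.snr_track[-1]) for r in last3]
    else:
        raise InvalidInputError(f"unknown estimator {estimator!r}")
    return SrtEstimate(srt_db=float(np.mean(per_run)), runs=runs,
                       estimator=estimator)


def measure_srt(listener: ListenerModel, seed: int = 0,
                estimator: str = "mean_last3_snr",
                integer_start: bool = False) -> SrtEstimate:
    """Full four-run adaptive procedure for one listener."""
    rng = np.random.default_rng(seed)
    runs = [run_staircase(listener, rng, integer_start=integer_start)
            for _ in range(N_RUNS)]
    return estimate_srt(runs, estimator=estimator)


def convergence_snr(listener: ListenerModel) -> float:
    """SNR at which P(>= 3 of 5 keywords correct) = 0.5 — the fixed point
    the 1-up/1-down rule tracks.  Solved numerically."""
    from scipy.optimize import brentq

    def g(snr):
        p = listener.p_correct(snr)
        return stats.binom.sf(UP_RULE_MAX_CORRECT, N_KEYWORDS, p) - 0.5

    lo, hi = listener.srt_true - 30.0, listener.srt_true + 30.0
    return float(brentq(g, lo, hi, xtol=1e-10))
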