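"""Harmonic model of comprehension versus stimulation phase.

Comprehension scores CS are measured at four phase shifts phi_n = n*90 deg
of the stimulation waveform.  Per subject, scores are centered on the
subject's four-phase mean, dCS(phi) = CS(phi) - CS_bar.  The cyclical
dependence of dCS on phase is decomposed as

    dCS(phi) = A0 + A1*cos(phi - phi1) + A2*cos(2*phi)
             = A0 + B1*sin(phi) + B2*cos(phi) + A2*cos(2*phi)

with B2 = A1*cos(phi1), B1 = A1*sin(phi1), so A1 = sqrt(B1^2 + B2^2) and
phi1 = atan2(B1, B2).  On the four study phases this is equivalent to a
length-4 discrete Fourier transform of dCS: A0 = a0, B2 = 2*Re(a1),
B1 = -2*Im(a1), A2 = a2 (used as an exact cross-check).

The model is fitted by pooled multiple linear regression over all
subject x phase observations, both by ordinary least squares and by
robust IRLS (Tukey bisquare, MAD scale); p-values are FDR-corrected
(Benjamini-Hochberg) within each model.  A bootstrap over subjects
compares the r^2 of the two fitting methods, and a best-phase-aligned
refit (relative phases 90/180/270 deg, no A2 term) probes whether
per-subject alignment adds signal or noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import IncompleteDesignError, InvalidInputError
from .waveform import _cosd, _sind

STUDY_PHASES = (0.0, 90.0, 180.0, 270.0)
ALIGNED_PHASES = (90.0, 180.0, 270.0)

SOURCES = ("target", "distractor", "sham")


def _wrap_deg(deg: float) -> float:
    """Reduce to [0, 360); float modulo of a tiny negative can return 360.0
    exactly, which must map to 0."""
    r = float(deg) % 360.0
    return 0.0 if r >= 360.0 else r
SCORE_COLUMNS = ("subject_id", "source", "phase_deg", "n_keywords", "n_correct")


# ---------------------------------------------------------------------------
# score table handling
# ---------------------------------------------------------------------------

def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form cohort score table and derive the CS column.

    Required columns: subject_id, source, phase_deg (NaN allowed for sham),
    n_keywords, n_correct.  CS = 100 * n_correct / n_keywords.
    """
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise InvalidInputError(f"score table missing columns: {missing}")
    if len(scores) == 0:
        raise InvalidInputError("score table is empty")
    bad_source = set(scores["source"]) - set(SOURCES)
    if bad_source:
        raise InvalidInputError(f"unknown stimulation sources: {sorted(bad_source)}")
    out = scores.copy()
    out["cs"] = 100.0 * out["n_correct"] / out["n_keywords"]
    bad = out.index[(out["cs"] < 0) | (out["cs"] > 100) | ~np.isfinite(out["cs"])]
    if len(bad):
        raise InvalidInputError(
            f"comprehension scores outside [0, 100] at rows {list(bad[:5])}"
        )
    return out


def _source_block(scores: pd.DataFrame, source: str) -> pd.DataFrame:
    if "cs" not in scores.columns:
        scores = validate_scores(scores)
    block = scores[scores["source"] == source]
    if len(block) == 0:
        raise IncompleteDesignError(f"no rows for source {source!r}")
    wide = block.pivot_table(index="subject_id", columns="phase_deg",
                             values="cs", aggfunc="first")
    want = list(STUDY_PHASES)
    if list(wide.columns.sort_values()) != want or wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist() if set(wide.columns) >= set(want) else wide.index.tolist()
        raise IncompleteDesignError(
            f"source {source!r}: subjects missing phases: {bad}"
        )
    return wide[want]


def center_scores(scores: pd.DataFrame, source: str) -> pd.DataFrame:
    """Per-subject mean-centered scores, long form.

    Returns columns subject_id, phase_deg, delta_cs, cs_mean; per subject
    the four delta_cs values sum to zero by construction.
    """
    wide = _source_block(scores, source)
    cs_mean = wide.mean(axis=1)
    delta = wide.sub(cs_mean, axis=0)
    long = delta.reset_index().melt(
        id_vars="subject_id", var_name="phase_deg", value_name="delta_cs"
    )
    long["phase_deg"] = long["phase_deg"].astype(float)
    long = long.merge(cs_mean.rename("cs_mean").reset_index(), on="subject_id")
    return long.sort_values(["subject_id", "phase_deg"]).reset_index(drop=True)


def best_phase_per_subject(scores: pd.DataFrame, source: str) -> pd.Series:
    """Phase with the highest comprehension score per subject.

    Ties resolve to the lowest phase (0 < 90 < 180 < 270 deg).
    """
    wide = _source_block(scores, source)
    return wide.idxmax(axis=1).astype(float)  # idxmax takes first = lowest phase


def align_to_best_phase(scores: pd.DataFrame, source: str) -> pd.DataFrame:
    """Center scores and re-index phases relative to each subject's best.

    The best phase itself is dropped; the remaining three delta_cs values
    are indexed by (phase - best) mod 360, i.e. 90/180/270 deg.
    """
    centered = center_scores(scores, source)
    best = best_phase_per_subject(scores, source)
    out = centered.merge(best.rename("best_phase").reset_index(), on="subject_id")
    out["phase_deg"] = (out["phase_deg"] - out["best_phase"]) % 360.0
    out = out[out["phase_deg"] != 0.0].drop(columns="best_phase")
    return out.sort_values(["subject_id", "phase_deg"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# discrete Fourier decomposition (exact, 4 phases)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierCoefficients:
    """Length-4 DFT of the centered scores at the four study phases."""

    a0: float
    a1: complex
    a2: float

    @property
    def a3(self) -> complex:
        return np.conj(self.a1)

    @property
    def A1(self) -> float:
        return 2.0 * abs(self.a1)

    @property
    def phi1_deg(self) -> float:
        # dCS = A1*cos(phi - phi1) has a1 = (A1/2)*exp(-i*phi1) under the
        # forward transform a_k = (1/4) sum dCS exp(-i k pi phi / 180)
        return _wrap_deg(np.degrees(-np.angle(self.a1)))

    @property
    def B1(self) -> float:
        return -2.0 * float(np.imag(self.a1))

    @property
    def B2(self) -> float:
        return 2.0 * float(np.real(self.a1))


def dft_coefficients(delta: np.ndarray) -> FourierCoefficients:
    """Forward DFT a_k = (1/4) sum_n dCS(phi_n) e^{-i k pi phi_n/180} of the
    4-vector of centered scores at (0, 90, 180, 270) deg."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (4,):
        raise InvalidInputError("dft_coefficients expects exactly 4 values")
    n = np.arange(4)
    a = np.array([np.sum(delta * np.exp(-1j * k * n * np.pi / 2)) / 4 for k in range(4)])
    return FourierCoefficients(a0=float(a[0].real), a1=complex(a[1]), a2=float(a[2].real))


def amplitude_ci(a1_hat: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the modulation amplitude A1 = |(B1, B2)|.

    On the balanced design (B1_hat, B2_hat) is approximately bivariate
    normal with independent components of common SE, so the estimate
    a1_hat/se follows a Rice distribution with noncentrality A1_true/se.
    The CI inverts that distribution (lower bound: sf(a1_hat) = alpha/2,
    floored at 0; upper: cdf(a1_hat) = alpha/2).  A Wald/delta interval
    for a vector norm under-covers when the amplitude is near the noise
    floor; this construction does not.
    """
    if se <= 0 or not np.isfinite(se):
        return (a1_hat, a1_hat)
    alpha = 1.0 - level
    x = a1_hat / se
    z = stats.norm.ppf(1.0 - alpha / 2)
    if x > 40.0:
        # far above the noise floor the Rice law is Gaussian; the numeric
        # inversion is ill-conditioned there
        return (float(a1_hat - z * se), float(a1_hat + z * se))

    def _sf(nu):
        return stats.rice.sf(x, max(nu, 1e-12))

    def _cdf(nu):
        return stats.rice.cdf(x, max(nu, 1e-12))

    hi_bracket = x + 10.0
    if _sf(0.0) >= alpha / 2:
        lo = 0.0  # amplitude indistinguishable from the noise floor
    else:
        lo = optimize.brentq(lambda nu: _sf(nu) - alpha / 2, 0.0, hi_bracket,
                             xtol=1e-10)
    if _cdf(0.0) <= alpha / 2:
        # the estimate is improbably small under every noncentrality; this
        # event has probability <= alpha/2 under any truth, so a degenerate
        # upper bound keeps the stated coverage
        hi = x
    else:
        hi = optimize.brentq(lambda nu: _cdf(nu) - alpha / 2, 0.0,
                             hi_bracket + 10.0, xtol=1e-10)
    return (float(lo * se), float(hi * se))


def amplitude_phase(B1: float, B2: float) -> tuple[float, float]:
    """(A1, phi1_deg) of the 360-deg-period modulation A1*cos(phi - phi1).

    A1 = sqrt(B1^2 + B2^2); phi1 = atan2(B1, B2) reduced to [0, 360).
    """
    A1 = float(np.hypot(B1, B2))
    phi1 = _wrap_deg(np.degrees(np.arctan2(B1, B2)))
    return A1, phi1


# ---------------------------------------------------------------------------
# pooled harmonic regression
# ---------------------------------------------------------------------------

COEF_NAMES_FULL = ("A0", "B1", "B2", "A2")
COEF_NAMES_ALIGNED = ("A0", "B1", "B2")


@dataclass(frozen=True)
class HarmonicFit:
    """Pooled regression fit of the harmonic phase model."""

    coef: pd.DataFrame      # index A0/B1/B2[/A2]; estimate, ci_low, ci_high, p_raw, p_fdr
    A1: float
    a1_ci: tuple[float, float]  # delta-method 95% CI of A1 (floored at 0)
    phi1_deg: float
    r2: float
    F: float
    p_model: float
    method: str             # "ols" | "robust"
    aligned: bool
    n_obs: int
    n_subjects: int

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        return bool(self.coef.loc[name, "p_fdr"] <= alpha)


def harmonic_design(phases_deg: np.ndarray, aligned: bool) -> np.ndarray:
    """Design matrix [1, sin(phi), cos(phi)(, cos(2 phi))]."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    cols = [np.ones_like(phases_deg),
            np.array([_sind(p) for p in phases_deg]),
            np.array([_cosd(p) for p in phases_deg])]
    if not aligned:
        cols.append(np.array([_cosd(2 * p) for p in phases_deg]))
    return np.column_stack(cols)


def _fit_arrays(y: np.ndarray, X: np.ndarray, method: str):
    """Fit y = X b by OLS or robust IRLS; return (params, conf_int, pvalues,
    fitted, weights)."""
    if method == "ols":
        res = sm.OLS(y, X).fit()
        weights = np.ones_like(y)
    elif method == "robust":
        res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(
            scale_est="mad", maxiter=200, tol=1e-10)
        weights = np.asarray(res.weights)
    else:
        raise InvalidInputError(f"unknown fitting method {method!r}")
    return res.params, res.conf_int(alpha=0.05), res.pvalues, res.fittedvalues, weights


def _r2_correlation(y: np.ndarray, fitted: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """r^2 as the squared Pearson correlation of observed and fitted
    values over the observations the fitting method retains.

    For OLS every observation is retained and this is the plain squared
    correlation.  The bisquare robust fit assigns weight exactly zero to
    gross outliers (residual beyond the tuning constant); those rejected
    points are excluded from its r^2.  On outlier-free data nothing is
    rejected and the two computations coincide; an r^2 that kept the
    outliers could never exceed the OLS value (OLS maximizes in-sample
    correlation over the design span), which would make the fits
    incomparable.
    """
    mask = np.ones(len(y), dtype=bool) if weights is None else \
        np.asarray(weights, dtype=float) > 0
    if mask.sum() < 3:
        return 0.0
    yk, fk = np.asarray(y)[mask], np.asarray(fitted)[mask]
    if np.std(yk) == 0 or np.std(fk) == 0:
        return 0.0
    return float(np.corrcoef(yk, fk)[0, 1] ** 2)


def fit_harmonic(
    centered: pd.DataFrame,
    method: str = "ols",
    aligned: bool = False,
) -> HarmonicFit:
    """Fit the harmonic phase model to long-form centered scores.

    `centered` needs columns subject_id, phase_deg, delta_cs (output of
    `center_scores` or `align_to_best_phase`).  One pooled regression over
    all subject x phase rows; 95% CIs from the coefficient covariance;
    p-values FDR-corrected within the model's coefficient set.
    """
    n_subjects = centered["subject_id"].nunique()
    if n_subjects < 2 and not aligned:
        pass  # single-subject fits are allowed (saturated interpolation)
    y = centered["delta_cs"].to_numpy(dtype=float)
    X = harmonic_design(centered["phase_deg"].to_numpy(), aligned)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidInputError("rank-deficient design (phases not distinct)")
    params, ci, p_raw, fitted, weights = _fit_arrays(y, X, method)
    names = COEF_NAMES_ALIGNED if aligned else COEF_NAMES_FULL
    p_fdr = multipletests(np.asarray(p_raw), method="fdr_bh")[1]
    coef = pd.DataFrame(
        {
            "estimate": np.asarray(params),
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
            "p_raw": np.asarray(p_raw),
            "p_fdr": p_fdr,
        },
        index=list(names),
    )
    A1, phi1 = amplitude_phase(coef.loc["B1", "estimate"], coef.loc["B2", "estimate"])
    se1 = (coef.loc["B1", "ci_high"] - coef.loc["B1", "ci_low"]) / (2 * 1.959964)
    se2 = (coef.loc["B2", "ci_high"] - coef.loc["B2", "ci_low"]) / (2 * 1.959964)
    a1_ci = amplitude_ci(A1, 0.5 * (se1 + se2))
    r2 = _r2_correlation(y, np.asarray(fitted), weights)
    k = X.shape[1] - 1
    dof = len(y) - X.shape[1]
    if dof > 0 and r2 < 1.0:
        F = (r2 / k) / ((1.0 - r2) / dof)
        p_model = float(stats.f.sf(F, k, dof))
    else:
        F, p_model = float("inf"), 0.0
    return HarmonicFit(
        coef=coef, A1=A1, a1_ci=(float(a1_ci[0]), float(a1_ci[1])),
        phi1_deg=phi1, r2=r2, F=float(F), p_model=p_model,
        method=method, aligned=aligned, n_obs=len(y), n_subjects=n_subjects,
    )


# ---------------------------------------------------------------------------
# bootstrap comparison of fitting methods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapComparison:
    """Paired bootstrap distribution of r^2 for OLS vs robust fits."""

    r2_ols: np.ndarray
    r2_robust: np.ndarray
    t: float
    p: float                # one-tailed, robust > ols
    n_boot: int
    seed: int
    n_skipped: int = field(default=0)


def _resample_subjects(centered: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    subjects = centered["subject_id"].unique()
    picks = rng.choice(subjects, size=subjects.size, replace=True)
    blocks = [centered[centered["subject_id"] == s] for s in picks]
    return pd.concat(blocks, ignore_index=True)


def bootstrap_r2_compare(
    centered: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    aligned: bool = False,
    unit: str = "subject",
) -> BootstrapComparison:
    """Bootstrap r^2 of OLS vs robust fits on the same resamples.

    Default resampling unit is the subject (each subject's full phase block
    kept together); `unit="row"` resamples individual observations.  The
    two r^2 distributions are compared with a paired one-tailed t-test of
    robust > standard.
    """
    rng = np.random.default_rng(seed)
    r2o, r2r = [], []
    n_skipped = 0
    y_all = centered["delta_cs"].to_numpy(dtype=float)
    X_all = harmonic_design(centered["phase_deg"].to_numpy(), aligned)
    n = len(centered)
    subjects = centered["subject_id"].to_numpy()
    uniq = np.unique(subjects)
    # index blocks per subject, so resampling is array indexing (fast path)
    blocks = {s: np.flatnonzero(subjects == s) for s in uniq}
    for _ in range(n_boot):
        if unit == "subject":
            picks = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([blocks[s] for s in picks])
        elif unit == "row":
            idx = rng.integers(0, n, size=n)
        else:
            raise InvalidInputError(f"unknown bootstrap unit {unit!r}")
        X, y = X_all[idx], y_all[idx]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            n_skipped += 1
            continue
        try:
            _, _, _, fit_o, w_o = _fit_arrays(y, X, "ols")
            _, _, _, fit_r, w_r = _fit_arrays(y, X, "robust")
        except Exception:
            n_skipped += 1
            continue
        r2o.append(_r2_correlation(y, np.asarray(fit_o), w_o))
        r2r.append(_r2_correlation(y, np.asarray(fit_r), w_r))
    r2o, r2r = np.asarray(r2o), np.asarray(r2r)
    t, p = stats.ttest_rel(r2r, r2o, alternative="greater")
    return BootstrapComparison(
        r2_ols=r2o, r2_robust=r2r, t=float(t), p=float(p),
        n_boot=n_boot, seed=seed, n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# amplitude and sham comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeComparison:
    """Two-tailed test of the A1 difference between two stimulation sources.

    The observed difference of the full-data A1 estimates is referred to a
    t distribution with n_subjects - 1 degrees of freedom, with the
    standard error taken from paired-bootstrap A1 differences (the same
    subject resample applied to both sources).
    """

    a1_a: float
    a1_b: float
    diff: float
    se_diff: float
    t: float
    df: int
    p: float
    n_boot: int
    seed: int


def compare_amplitudes(
    centered_a: pd.DataFrame,
    centered_b: pd.DataFrame,
    method: str = "robust",
    n_boot: int = 2000,
    seed: int = 0,
) -> AmplitudeComparison:
    """Compare the 360-deg modulation amplitudes A1 of two sources."""
    subj_a = np.sort(centered_a["subject_id"].unique())
    subj_b = np.sort(centered_b["subject_id"].unique())
    if subj_a.size != subj_b.size:
        raise IncompleteDesignError("amplitude comparison needs matched cohorts")
    fit_a = fit_harmonic(centered_a, method=method)
    fit_b = fit_harmonic(centered_b, method=method)
    diff = fit_a.A1 - fit_b.A1
    rng = np.random.default_rng(seed)
    sa = centered_a["subject_id"].to_numpy()
    sb = centered_b["subject_id"].to_numpy()
    blocks_a = {s: np.flatnonzero(sa == s) for s in subj_a}
    blocks_b = {s: np.flatnonzero(sb == s) for s in subj_b}
    ya = centered_a["delta_cs"].to_numpy(dtype=float)
    yb = centered_b["delta_cs"].to_numpy(dtype=float)
    Xa = harmonic_design(centered_a["phase_deg"].to_numpy(), aligned=False)
    Xb = harmonic_design(centered_b["phase_deg"].to_numpy(), aligned=False)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, subj_a.size, size=subj_a.size)
        ia = np.concatenate([blocks_a[subj_a[j]] for j in pick])
        ib = np.concatenate([blocks_b[subj_b[j]] for j in pick])
        pa = _fit_arrays(ya[ia], Xa[ia], method)[0]
        pb = _fit_arrays(yb[ib], Xb[ib], method)[0]
        a1a, _ = amplitude_phase(pa[1], pa[2])
        a1b, _ = amplitude_phase(pb[1], pb[2])
        diffs[i] = a1a - a1b
    se = float(np.std(diffs, ddof=1))
    df = int(subj_a.size - 1)
    if se == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = diff / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return AmplitudeComparison(
        a1_a=fit_a.A1, a1_b=fit_b.A1, diff=float(diff), se_diff=se,
        t=float(t_stat), df=df, p=p, n_boot=n_boot, seed=seed,
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict


def compare_to_sham(
    scores: pd.DataFrame,
    best_target_phase: float = 0.0,
    best_distractor_phase: float = 180.0,
) -> AnovaResult:
    """One-way ANOVA of comprehension at the best phases versus sham.

    Groups: target at its best phase, distractor at its best phase, and
    sham; all three must contain the same subjects (paired design).
    """
    scores = validate_scores(scores)
    tgt = scores[(scores["source"] == "target")
                 & (scores["phase_deg"] == best_target_phase)]
    dis = scores[(scores["source"] == "distractor")
                 & (scores["phase_deg"] == best_distractor_phase)]
    sham = scores[scores["source"] == "sham"]
    groups = {"target": tgt, "distractor": dis, "sham": sham}
    sizes = {k: len(v) for k, v in groups.items()}
    if len(set(sizes.values())) != 1 or 0 in sizes.values():
        raise IncompleteDesignError(f"unequal or empty ANOVA groups: {sizes}")
    arrays = [g["cs"].to_numpy(dtype=float) for g in groups.values()]
    F, p = stats.f_oneway(*arrays)
    n = sum(sizes.values())
    return AnovaResult(
        F=float(F), df_between=2, df_within=n - 3, p=float(p),
        group_means={k: float(v["cs"].mean()) for k, v in groups.items()},
    )
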