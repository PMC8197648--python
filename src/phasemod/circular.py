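"""Circular statistics for per-subject best stimulation phases.

Each subject contributes one angle: the stimulation phase that produced
their highest comprehension score.  The sample of angles is summarized by
its circular mean, resultant vector length R and angular deviation
sqrt(2(1-R)); tested for uniformity (Rayleigh); fitted with a von Mises
distribution (ML mu = circular mean, kappa by inverting A(kappa) =
I1(kappa)/I0(kappa) = R) whose goodness of fit is assessed with Watson's
one-sample U^2 test; and two samples can be compared for equal
concentration with Fisher's homogeneity test.

Angles are degrees at the API surface and radians internally.  With the
study design the angles take only four discrete values (0/90/180/270
deg); the continuous-distribution tests are then approximations, and an
optional uniform jitter of +/-45 deg is available for goodness-of-fit
stability (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import DegenerateInputError, InvalidInputError

KAPPA_CAP = 1e6  # reported when R == 1 (point mass); flagged in the fit


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float
    R: float
    ang_dev_rad: float
    n: int


def _to_radians(angles_deg) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise InvalidInputError("expected a non-empty 1-D sample of angles")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("angles must be finite")
    return np.radians(a % 360.0)


def resultant_length(angles_deg) -> float:
    """Mean resultant vector length R in [0, 1]."""
    a = _to_radians(angles_deg)
    return float(np.abs(np.mean(np.exp(1j * a))))


def angular_deviation(R: float) -> float:
    """Angular deviation s = sqrt(2(1-R)), in radians."""
    return float(np.sqrt(max(2.0 * (1.0 - R), 0.0)))  # R=1 up to float eps


def circular_summary(angles_deg) -> CircularSummary:
    """Circular mean direction, resultant length and angular deviation."""
    a = _to_radians(angles_deg)
    z = np.mean(np.exp(1j * a))
    R = float(np.abs(z))
    if R > 0:
        mean_deg = float(np.degrees(np.angle(z)) % 360.0)
        if mean_deg >= 360.0:  # float modulo of a tiny negative angle
            mean_deg = 0.0
    else:
        mean_deg = float("nan")
    return CircularSummary(mean_deg=mean_deg, R=R,
                           ang_dev_rad=angular_deviation(R), n=a.size)


# ---------------------------------------------------------------------------
# Rayleigh test of uniformity
# ---------------------------------------------------------------------------

def rayleigh_p(n: int, R: float) -> float:
    """Rayleigh uniformity p-value from sample size and resultant length.

    Uses Z = n R^2 with the standard finite-n series correction
    (Zar / Fisher): p = e^{-Z} [1 + (2Z - Z^2)/(4n)
    - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)].
    """
    if n < 1 or not (0.0 <= R <= 1.0 + 1e-12):
        raise InvalidInputError("need n >= 1 and R in [0, 1]")
    Z = n * R * R
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """(Z, p) of the Rayleigh test on a sample of angles (degrees)."""
    a = _to_radians(angles_deg)
    n = a.size
    R = resultant_length(angles_deg)
    if n < 4:
        # exact permutation is impossible for a continuous null; fall back
        # to Monte Carlo under uniformity
        p = monte_carlo_rayleigh_p(n, R, n_draws=50_000, seed=0)
        return float(n * R * R), p
    return float(n * R * R), rayleigh_p(n, R)


def monte_carlo_rayleigh_p(n: int, R: float, n_draws: int = 50_000,
                           seed: int = 0) -> float:
    """Monte-Carlo null of the Rayleigh statistic: P(R_null >= R) under
    uniform angles.  Independent oracle for `rayleigh_p`."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * np.pi, size=(n_draws, n))
    R_null = np.abs(np.mean(np.exp(1j * theta), axis=1))
    return float(np.mean(R_null >= R))


# ---------------------------------------------------------------------------
# von Mises fit and Watson goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VonMisesFit:
    mu_deg: float
    kappa: float
    watson_u2: float
    watson_p: float
    kappa_capped: bool
    n: int
    jittered: bool


def _A1(kappa: float) -> float:
    """Mean resultant length of a von Mises(mu, kappa): I1(k)/I0(k)."""
    # scaled Bessel ratio is stable for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_R(R: float) -> tuple[float, bool]:
    """ML concentration: invert A(kappa) = R.  Returns (kappa, capped)."""
    if R <= 0.0:
        return 0.0, False
    if R >= _A1(KAPPA_CAP):
        return KAPPA_CAP, True
    kappa = optimize.brentq(lambda k: _A1(k) - R, 0.0, KAPPA_CAP, xtol=1e-12)
    return float(kappa), False


def watson_u2(angles_deg, mu_deg: float, kappa: float) -> tuple[float, float]:
    """Watson's one-sample U^2 goodness-of-fit test against von Mises.

    The sample is transformed through the fitted CDF; U^2 is computed on
    the resulting [0, 1) values, and the p-value uses Stephens' modified
    statistic with the asymptotic series
    p = 2 sum_{m>=1} (-1)^{m-1} exp(-2 m^2 pi^2 U*^2).
    The parameters being estimated from the same sample makes the p-value
    approximate (slightly conservative).
    """
    a = _to_radians(angles_deg)
    n = a.size
    # wrap angles to (-pi, pi] around mu; PIT through the fitted CDF
    x = np.angle(np.exp(1j * (a - np.radians(mu_deg))))
    if kappa > 1e-8:
        u = stats.vonmises.cdf(x, kappa)
    else:
        u = (x + np.pi) / (2 * np.pi)
    u = np.sort(u)
    i = np.arange(1, n + 1)
    ubar = float(np.mean(u))
    U2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2)
               - n * (ubar - 0.5) ** 2 + 1.0 / (12 * n))
    U2_mod = (U2 - 0.1 / n + 0.1 / n**2) * (1.0 + 0.8 / n)
    m = np.arange(1, 51)
    p = float(2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * U2_mod)))
    return U2, float(min(max(p, 0.0), 1.0))


def fit_von_mises(angles_deg, jitter_halfwidth_deg: float = 0.0,
                  seed: int = 0) -> VonMisesFit:
    """ML von Mises fit with Watson U^2 goodness of fit.

    With `jitter_halfwidth_deg` > 0 a uniform jitter is added to each
    angle before fitting (useful when angles are discretized to the four
    study phases); off by default and recorded in the result.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 4:
        raise DegenerateInputError("von Mises fit needs at least 4 angles")
    jittered = jitter_halfwidth_deg > 0
    if jittered:
        rng = np.random.default_rng(seed)
        a = a + rng.uniform(-jitter_halfwidth_deg, jitter_halfwidth_deg, a.size)
    summ = circular_summary(a)
    kappa, capped = kappa_from_R(summ.R)
    mu = summ.mean_deg if summ.R > 0 else 0.0
    u2, p = watson_u2(a, mu, kappa)
    return VonMisesFit(mu_deg=mu, kappa=kappa, watson_u2=u2, watson_p=p,
                       kappa_capped=capped, n=a.size, jittered=jittered)


def sample_von_mises(mu_deg: float, kappa: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw `n` angles (degrees in [0, 360)) from von Mises(mu, kappa)."""
    rng = np.random.default_rng(seed)
    a = rng.vonmises(np.radians(mu_deg), kappa, size=n)
    return np.degrees(a) % 360.0


# ---------------------------------------------------------------------------
# two-sample concentration homogeneity
# ---------------------------------------------------------------------------

def concentration_homogeneity(angles_a_deg, angles_b_deg) -> tuple[float, float]:
    """Fisher's two-sample test of equal concentration; returns (stat, p).

    Regime chosen by the pooled mean resultant length rbar
    (rbar = (n1*R1 + n2*R2)/(n1 + n2)), following the standard
    three-regime construction of circular-statistics references:

    - rbar < 0.45: z-test on the variance-stabilizing transform
      g1(R) = asin(2R * sqrt(3/8)), SE = sqrt(3/8 * (1/(n1-4) + 1/(n2-4)));
    - 0.45 <= rbar <= 0.70: z-test on g2(R) = asinh((R - 1.0894)/0.25789),
      SE = 0.893 * sqrt(1/(n1-3) + 1/(n2-3));
    - rbar > 0.70: variance ratio [n1(1-R1)/(n1-1)] / [n2(1-R2)/(n2-1)]
      referred to F(n1-1, n2-1).

    Two-tailed throughout.
    """
    a = _to_radians(angles_a_deg)
    b = _to_radians(angles_b_deg)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 5:
        raise DegenerateInputError("concentration test needs >= 5 angles per sample")
    R1 = float(np.abs(np.mean(np.exp(1j * a))))
    R2 = float(np.abs(np.mean(np.exp(1j * b))))
    rbar = (n1 * R1 + n2 * R2) / (n1 + n2)
    if rbar < 0.45:
        g = lambda R: np.arcsin(min(2.0 * R * np.sqrt(3.0 / 8.0), 1.0))
        se = np.sqrt(3.0 / 8.0 * (1.0 / (n1 - 4) + 1.0 / (n2 - 4)))
        z = (g(R1) - g(R2)) / se
        return float(z), float(2 * stats.norm.sf(abs(z)))
    if rbar <= 0.70:
        g = lambda R: np.arcsinh((R - 1.0894) / 0.25789)
        se = 0.893 * np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (g(R1) - g(R2)) / se
        return float(z), float(2 * stats.norm.sf(abs(z)))
    # high concentration: ratio of circular dispersions ~ F
    v1 = n1 * (1.0 - R1) / (n1 - 1)
    v2 = n2 * (1.0 - R2) / (n2 - 1)
    if v1 == 0.0 and v2 == 0.0:
        return 1.0, 1.0
    if v2 == 0.0 or v1 == 0.0:
        return float("inf"), 0.0
    F = v1 / v2 if v1 > v2 else v2 / v1
    dfn, dfd = (n1 - 1, n2 - 1) if v1 > v2 else (n2 - 1, n1 - 1)
    p = float(2 * stats.f.sf(F, dfn, dfd))
    return float(F), float(min(p, 1.0))
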