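"""Circular statistics for angular heading data.

Implements the tests applied to walking-direction samples: the two-sample
Watson U-squared test on pooled circular ranks, the Watson-Williams
high-concentration F-test for equal mean directions, Hotelling's paired
second-order test (per-subject difference of unit vectors, Hotelling T**2
against zero), and the Harrison-Kanji two-factor ANOVA for circular data.
Descriptive helpers (circular mean, resultant length, circular SEM) follow
the standard directional-statistics definitions.

Angles are accepted in degrees by default (``degrees=False`` switches to
radians); all tests are invariant to a common rotation of every angle and to
the unit declaration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "wrap_angles_deg",
    "circ_mean_deg",
    "circ_r",
    "circ_sem_deg",
    "TestResult",
    "watson_u2",
    "watson_williams",
    "hotelling_paired",
    "circular_anova_hk",
]


def _to_rad(angles, degrees: bool) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    return np.deg2rad(a) if degrees else a


def wrap_angles_deg(angles_deg) -> np.ndarray:
    """Reduce angles to the interval (-180, 180]."""
    a = np.asarray(angles_deg, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out


def circ_r(angles, degrees: bool = True) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    a = _to_rad(angles, degrees)
    return float(np.abs(np.mean(np.exp(1j * a))))


def circ_mean_deg(angles_deg) -> float:
    """Circular mean direction, in degrees in (-180, 180]."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    m = np.mean(np.exp(1j * a))
    if np.abs(m) == 0:
        raise ValueError("mean direction undefined: zero resultant")
    return float(wrap_angles_deg(np.rad2deg(np.angle(m))))


def _kappa_ml(rbar: float) -> float:
    """Best-Fisher approximation to the von Mises concentration parameter."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    denom = rbar ** 3 - 4 * rbar ** 2 + 3 * rbar
    return 1.0 / denom if denom > 0 else 1e6


def circ_sem_deg(angles_deg) -> float:
    """Circular standard error of the mean direction, in degrees.

    sigma = 1 / sqrt(n * R-bar * kappa-hat), the large-kappa standard error
    of a von Mises mean direction.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = len(a)
    if n < 2:
        return 0.0
    rbar = circ_r(a)
    if rbar <= 0:
        return 180.0
    kappa = _kappa_ml(rbar)
    return float(np.rad2deg(1.0 / math.sqrt(n * rbar * kappa)))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    name: str
    df: Optional[tuple] = None
    warning: Optional[str] = None
    details: Optional[dict] = None


# ---------------------------------------------------------------------------
# Watson two-sample U2
# ---------------------------------------------------------------------------

def _watson_u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Watson U2 from pooled circular ranks; ties by mid-ranks.

    d_k is the difference of the two samples' empirical CDFs after each
    pooled order statistic; tied pooled values are processed as one group and
    assigned the midpoint of the pre/post-group d (mid-rank convention).
    U2 = (n1 n2 / N^2) * (sum d_k^2 - (sum d_k)^2 / N).
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate((a, b))
    labels = np.concatenate((np.zeros(n1, dtype=int), np.ones(n2, dtype=int)))
    order = np.argsort(pooled, kind="mergesort")
    vals = pooled[order]
    labs = labels[order]
    N = n1 + n2
    d = np.empty(N)
    i = j = 0
    k = 0
    d_prev = 0.0
    while k < N:
        k2 = k
        while k2 + 1 < N and vals[k2 + 1] == vals[k]:
            k2 += 1
        # process tie group [k, k2]
        for m in range(k, k2 + 1):
            if labs[m] == 0:
                i += 1
            else:
                j += 1
        d_after = i / n1 - j / n2
        d[k:k2 + 1] = 0.5 * (d_prev + d_after) if k2 > k else d_after
        d_prev = d_after
        k = k2 + 1
    return float(n1 * n2 / N ** 2 * (np.sum(d ** 2) - np.sum(d) ** 2 / N))


def _watson_u2_pvalue_asymptotic(u2: float, n_terms: int = 60) -> float:
    """Asymptotic tail probability of Watson's U2 distribution.

    For moderate/large u the alternating series
    2 * sum_m (-1)^(m-1) exp(-2 m^2 pi^2 u) converges fast; for small u it
    does not, and the Jacobi-theta transformed form
    1 - (2 pi u)^(-1/2) * sum_k exp(-(2k+1)^2 / (8u)) is used instead.
    """
    if u2 <= 0:
        return 1.0
    if u2 < 0.12:
        k = np.arange(0, n_terms)
        s = 2.0 * np.sum(np.exp(-(2 * k + 1) ** 2 / (8.0 * u2)))
        p = 1.0 - s / math.sqrt(2.0 * math.pi * u2)
    else:
        m = np.arange(1, n_terms + 1)
        p = 2.0 * np.sum((-1.0) ** (m - 1)
                         * np.exp(-2.0 * m ** 2 * np.pi ** 2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2(sample_a, sample_b, degrees: bool = True,
              p_method: str = "asymptotic",
              n_permutations: int = 999,
              seed: Optional[int] = None) -> TestResult:
    """Two-sample Watson U2 test for a common angular distribution.

    p_method="asymptotic" uses the limiting Watson distribution (accurate
    even for modest n); "permutation" estimates p by random reassignment of
    the pooled sample, which is exact up to Monte-Carlo error and preferable
    for very small samples.
    """
    a = _to_rad(sample_a, degrees) % (2 * np.pi)
    b = _to_rad(sample_b, degrees) % (2 * np.pi)
    if len(a) < 4 or len(b) < 4:
        raise ValueError("each sample needs at least 4 angles")
    u2 = _watson_u2_statistic(a, b)
    if p_method == "asymptotic":
        p = _watson_u2_pvalue_asymptotic(u2)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate((a, b))
        n1 = len(a)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _watson_u2_statistic(perm[:n1], perm[n1:]) >= u2:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")
    return TestResult(statistic=u2, p_value=p, name="watson_u2",
                      details={"n_a": len(a), "n_b": len(b)})


# ---------------------------------------------------------------------------
# Watson-Williams
# ---------------------------------------------------------------------------

def watson_williams(*samples, degrees: bool = True,
                    rbar_warn: float = 0.7) -> TestResult:
    """Watson-Williams F-test for equality of mean directions (q samples).

    High-concentration test: F = K * (N-q)/(q-1) * (sum R_i - R)/(N - sum R_i)
    with the standard correction K = 1 + 3/(8 kappa-hat); p from F(q-1, N-q).
    Valid for concentrated data — a warning flag is set when the weighted
    mean resultant length falls below ``rbar_warn``.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    rads = [_to_rad(s, degrees) for s in samples]
    ns = np.array([len(r) for r in rads])
    if np.any(ns < 2):
        raise ValueError("each sample needs at least 2 angles")
    N = int(np.sum(ns))
    q = len(rads)
    resultants = np.array([np.abs(np.sum(np.exp(1j * r))) for r in rads])
    R = float(np.abs(np.sum(np.concatenate([np.exp(1j * r) for r in rads]))))
    sum_Ri = float(np.sum(resultants))
    rbar_w = sum_Ri / N
    warning = None
    if rbar_w < rbar_warn:
        warning = (f"mean resultant length {rbar_w:.3f} < {rbar_warn}: "
                   "Watson-Williams assumptions questionable")
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    kappa = _kappa_ml(rbar_w)
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - sum_Ri
    if denom <= 0:
        F = math.inf if sum_Ri - R > 1e-12 else 0.0
    else:
        F = K * (N - q) / (q - 1) * (sum_Ri - R) / denom
        F = max(F, 0.0)
    p = float(stats.f.sf(F, q - 1, N - q)) if math.isfinite(F) else 0.0
    return TestResult(statistic=F, p_value=p, name="watson_williams",
                      df=(q - 1, N - q), warning=warning,
                      details={"rbar_weighted": rbar_w, "kappa": kappa})


# ---------------------------------------------------------------------------
# Hotelling paired second-order test
# ---------------------------------------------------------------------------

def hotelling_paired(sample_a, sample_b, degrees: bool = True) -> TestResult:
    """Hotelling's pair-sample test for a common mean direction.

    Per subject, the difference of the two conditions' unit vectors
    d_i = (cos a_i - cos b_i, sin a_i - sin b_i) is formed; Hotelling's T**2
    tests whether the bivariate mean of d is zero.
    F = (n-2)/(2(n-1)) * T**2 with df (2, n-2).
    """
    a = _to_rad(sample_a, degrees)
    b = _to_rad(sample_b, degrees)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = np.column_stack((np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)))
    dbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False, ddof=1)
    det = float(np.linalg.det(S))
    if det <= np.finfo(float).tiny:
        # degenerate spread: identical difference vectors across subjects
        if np.allclose(dbar, 0.0):
            return TestResult(statistic=0.0, p_value=1.0,
                              name="hotelling_paired", df=(2, n - 2))
        rank = np.linalg.matrix_rank(S, tol=1e-12)
        if rank == 0 or np.allclose(d - dbar, 0.0):
            return TestResult(statistic=math.inf, p_value=0.0,
                              name="hotelling_paired", df=(2, n - 2),
                              warning="singular covariance: zero within-sample spread")
        S = S + 1e-12 * np.eye(2)  # rank-1 spread off the mean axis
    t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    F = (n - 2) / (2.0 * (n - 1)) * t2
    p = float(stats.f.sf(F, 2, n - 2))
    return TestResult(statistic=F, p_value=p, name="hotelling_paired",
                      df=(2, n - 2), details={"t2": t2, "n": n})


# ---------------------------------------------------------------------------
# Harrison-Kanji two-factor circular ANOVA
# ---------------------------------------------------------------------------

def circular_anova_hk(angles, factor_a, factor_b,
                      degrees: bool = True) -> dict[str, TestResult]:
    """Harrison-Kanji two-factor ANOVA for circular data (the "hk test").

    Decomposes squared resultant lengths per cell/row/column into main
    effects, interaction and residual.  For concentrated data
    (kappa-hat > 2) F-ratios with df (p-1, q-1, (p-1)(q-1); n-pq) are used;
    for low-to-moderate concentration a chi-square approximation with
    inflation factor 2/(1 - rho^2), rho = I1(kappa)/I0(kappa), applies, on
    2 x df degrees of freedom (both components of each mean vector
    fluctuate, so each angular effect df carries two chi-square df; this
    keeps the test calibrated down to the uniform limit, where the statistic
    reduces to the classical Rayleigh-type decomposition).  Repeated
    measurements across factor levels are treated as independent groups.
    """
    alpha = _to_rad(angles, degrees)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(alpha) == len(fa) == len(fb)):
        raise ValueError("angles and factor labels must align")
    levels_a = np.unique(fa)
    levels_b = np.unique(fb)
    p, q = len(levels_a), len(levels_b)
    if p < 2 or q < 2:
        raise ValueError("each factor needs at least two levels")
    n = len(alpha)
    z = np.exp(1j * alpha)
    for la in levels_a:
        for lb in levels_b:
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty design cell: ({la!r}, {lb!r})")

    tR = float(np.abs(np.sum(z)))
    kappa = _kappa_ml(tR / n)

    def ssq(mask_groups) -> float:
        return float(sum(np.abs(np.sum(z[m])) ** 2 / np.sum(m) for m in mask_groups))

    rows = [fa == la for la in levels_a]
    cols = [fb == lb for lb in levels_b]
    cells = [(fa == la) & (fb == lb) for la in levels_a for lb in levels_b]
    base = tR ** 2 / n
    eff_a = ssq(rows) - base
    eff_b = ssq(cols) - base
    eff_cells = ssq(cells) - base
    eff_i = eff_cells - eff_a - eff_b
    eff_r = n - (eff_cells + base)
    df_a, df_b = p - 1, q - 1
    df_i = (p - 1) * (q - 1)
    df_r = n - p * q
    if df_r <= 0:
        raise ValueError("no residual degrees of freedom (one observation per cell)")

    results: dict[str, TestResult] = {}
    eps = n * 1e-12  # numerical floor for resultant-length sums
    if kappa > 2.0:
        ms_r = eff_r / df_r
        for key, eff, df in (("factor_a", eff_a, df_a),
                             ("factor_b", eff_b, df_b),
                             ("interaction", eff_i, df_i)):
            eff = max(eff, 0.0)
            if eff_r > eps:
                F = eff / df / ms_r
            else:
                # zero residual spread: any effect is infinitely resolvable
                F = 0.0 if eff <= eps else math.inf
            p = float(stats.f.sf(F, df, df_r)) if math.isfinite(F) else 0.0
            results[key] = TestResult(statistic=F, p_value=p,
                                      name=f"hk_{key}", df=(df, df_r),
                                      details={"kappa": kappa, "branch": "F"})
    else:
        rho = float(special.iv(1, kappa) / special.iv(0, kappa))
        f_corr = 2.0 / (1.0 - rho ** 2)
        for key, eff, df in (("factor_a", eff_a, df_a),
                             ("factor_b", eff_b, df_b),
                             ("interaction", eff_i, df_i)):
            chi = max(f_corr * eff, 0.0)
            results[key] = TestResult(statistic=chi,
                                      p_value=float(stats.chi2.sf(chi, 2 * df)),
                                      name=f"hk_{key}", df=(2 * df,),
                                      details={"kappa": kappa, "branch": "chi2"})
    return results
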