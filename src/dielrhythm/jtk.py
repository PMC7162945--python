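"""Nonparametric rhythmicity detection (JTK_CYCLE-style exact test).

The test asks whether a time series follows a cosine of a candidate
period and phase *in rank order*.  For each (period, lag) combination a
reference cosine is evaluated at the sample times and converted to
midranks; the Kendall-type statistic

    S = sum_{i<j} sign(x_j - x_i) * sign(ref_j - ref_i)

measures concordance between the series and the reference.  Because the
reference ranks contain ties (a sampled cosine is symmetric about its
peak), the null distribution of S is computed exactly, conditioned on
the reference tie pattern, under the hypothesis that the series values
are exchangeable.  The minimum one-sided exact P over the (period, lag)
grid is Bonferroni-adjusted by the number of combinations, and the
winning lag is the phase estimate: the ZT time of the fitted peak.

The exact null uses the classical decomposition of the
Jonckheere-Terpstra statistic into independent Mann-Whitney components,
whose generating function is the Gaussian (q-) binomial coefficient, so
the distribution is obtained by exact integer convolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import rankdata

_COS_DECIMALS = 9  # rounding before ranking so symmetric cosine values tie exactly


class JtkError(ValueError):
    pass


@dataclass(frozen=True)
class JtkConfig:
    """Search grid and adjustment for the rhythmicity test.

    periods_h : candidate periods (default only 24 h — a 14-point/26-h
        diel course cannot resolve other periods usefully).
    lag_step_h : spacing of the phase grid; the grid covers [0, period),
        so anti-phase patterns are part of the search (two-sidedness).
    exact_n_max : largest series length for which the exact null is
        computed (guards against huge convolutions).
    """

    periods_h: tuple[float, ...] = (24.0,)
    lag_step_h: float = 2.0
    exact_n_max: int = 25

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.periods_h):
            raise JtkError("periods must be positive")
        if self.lag_step_h <= 0:
            raise JtkError("lag step must be positive")

    def lags_for(self, period: float) -> np.ndarray:
        return np.arange(0.0, period, self.lag_step_h)

    @property
    def n_combinations(self) -> int:
        return int(sum(len(self.lags_for(p)) for p in self.periods_h))


@dataclass
class JtkResult:
    series_id: str
    best_period_h: float
    best_lag_h: float
    phase_zt: float
    tau: float
    p_exact: float
    p_adjusted: float
    amplitude_est: float
    constant: bool = False


def reference_rank_pattern(
    period_h: float, lag_h: float, sample_times_zt: np.ndarray
) -> np.ndarray:
    """Midranks of a reference cosine peaking at ZT ``lag_h``."""
    if period_h <= 0:
        raise JtkError("period must be positive")
    t = np.asarray(sample_times_zt, dtype=float)
    ref = np.cos(2.0 * np.pi * (t - lag_h) / period_h)
    return rankdata(np.round(ref, _COS_DECIMALS), method="average")


def kendall_S(x: np.ndarray, ref_ranks: np.ndarray) -> tuple[int, int, int]:
    """Kendall-type S against a (possibly tied) reference pattern.

    Returns ``(S, concordant, discordant)``; pairs tied in either vector
    contribute zero.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(ref_ranks, dtype=float)
    if x.shape != r.shape:
        raise JtkError("series and reference lengths differ")
    if x.size < 3:
        raise JtkError("need at least 3 observations")
    i, j = np.triu_indices(x.size, k=1)
    prod = np.sign(x[j] - x[i]) * np.sign(r[j] - r[i])
    conc = int(np.sum(prod > 0))
    disc = int(np.sum(prod < 0))
    return conc - disc, conc, disc


def _tie_groups(ref_ranks: np.ndarray) -> tuple[int, ...]:
    """Sizes of the reference tie groups, as a sorted tuple."""
    _, counts = np.unique(np.asarray(ref_ranks, dtype=float), return_counts=True)
    return tuple(sorted(int(c) for c in counts))


@lru_cache(maxsize=None)
def _gaussian_binomial(m: int, n: int) -> tuple[int, ...]:
    """Coefficients of the Gaussian binomial [m+n choose n]_q.

    Coefficient ``u`` counts the interleavings of two blocks of sizes m
    and n with exactly u between-block inversions — i.e. the unnormalized
    null pmf of the Mann-Whitney U statistic.
    """
    if m == 0 or n == 0:
        return (1,)
    # Pascal-type recurrence: [m+n, n]_q = [m+n-1, n-1]_q + q^n [m+n-1, n]_q
    a = _gaussian_binomial(m, n - 1)
    b = _gaussian_binomial(m - 1, n)
    out = [0] * (m * n + 1)
    for u, c in enumerate(a):
        out[u] += c
    for u, c in enumerate(b):
        out[u + n] += c
    return tuple(out)


@lru_cache(maxsize=None)
def _jt_counts(group_sizes: tuple[int, ...]) -> tuple[int, ...]:
    """Unnormalized exact null distribution of the JT statistic.

    JT (the number of concordant between-group pairs) decomposes into
    independent Mann-Whitney components, one per group against the union
    of the preceding groups; the count generating function is therefore
    the product of Gaussian binomials (the q-multinomial, symmetric in
    the group sizes).
    """
    counts = [1]
    m = 0
    for n in group_sizes:
        if m:
            g = _gaussian_binomial(m, n)
            new = [0] * (len(counts) + len(g) - 1)
            for u1, c1 in enumerate(counts):
                if c1:
                    for u2, c2 in enumerate(g):
                        new[u1 + u2] += c1 * c2
            counts = new
        m += n
    return tuple(counts)


def exact_null_distribution(
    ref_ranks: np.ndarray, n_max: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of S for a given reference tie pattern.

    The series is assumed exchangeable with no ties among its values;
    the distribution is over ``S = 2*JT - P`` where P is the number of
    pairs not tied in the reference.  Returns ``(s_values, pmf)`` with
    ``s_values`` ascending; the pmf is symmetric about zero and sums
    to 1.
    """
    r = np.asarray(ref_ranks, dtype=float)
    n = r.size
    if n > n_max:
        raise JtkError(f"series length {n} exceeds exact-null limit {n_max}")
    sizes = _tie_groups(r)
    pair_total = n * (n - 1) // 2
    tied_pairs = sum(k * (k - 1) // 2 for k in sizes)
    p_pairs = pair_total - tied_pairs
    counts = np.array(_jt_counts(sizes), dtype=float)
    s_values = 2 * np.arange(counts.size) - p_pairs
    return s_values, counts / counts.sum()


def upper_tail_p(s_obs: float, s_values: np.ndarray, pmf: np.ndarray) -> float:
    """P(S >= s_obs) under the exact null."""
    return float(pmf[s_values >= s_obs - 1e-9].sum())


def permutation_oracle_p(x: np.ndarray, ref_ranks: np.ndarray) -> float:
    """Brute-force exact upper-tail P by enumerating all permutations.

    Test oracle only (n <= 8); independent of the convolution route.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n > 8:
        raise JtkError("permutation oracle limited to n <= 8")
    s_obs, _, _ = kendall_S(x, ref_ranks)
    hits = 0
    total = 0
    values = rankdata(x, method="ordinal")  # distinct surrogate values
    for perm in itertools.permutations(values):
        s, _, _ = kendall_S(np.array(perm, dtype=float), ref_ranks)
        total += 1
        if s >= s_obs:
            hits += 1
    return hits / total


def _amplitude_estimate(
    x: np.ndarray, times: np.ndarray, period: float, lag: float
) -> float:
    """Half peak-to-trough of the least-squares cosine fit at the winning lag."""
    ref = np.cos(2.0 * np.pi * (times - lag) / period)
    design = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    fitted = design @ coef
    return float((fitted.max() - fitted.min()) / 2.0)


def jtk_test(
    series: np.ndarray,
    times: np.ndarray,
    config: JtkConfig = JtkConfig(),
    series_id: str = "",
) -> JtkResult:
    """Run the exact rank test over the (period, lag) grid.

    Returns the minimizing combination (ties broken toward the earlier
    period and smaller lag), its exact one-sided P, and the Bonferroni
    adjustment ``min(1, p * n_combinations)``.  Constant series are
    flagged and returned with tau 0 and P 1.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.shape != t.shape:
        raise JtkError("series and times lengths differ")
    if np.ptp(x) == 0.0:
        return JtkResult(
            series_id=series_id,
            best_period_h=config.periods_h[0],
            best_lag_h=0.0,
            phase_zt=0.0,
            tau=0.0,
            p_exact=1.0,
            p_adjusted=1.0,
            amplitude_est=0.0,
            constant=True,
        )
    best = None  # (p, period, lag, s, p_pairs)
    for period in config.periods_h:
        for lag in config.lags_for(period):
            ref = reference_rank_pattern(period, lag, t)
            s_vals, pmf = exact_null_distribution(ref, n_max=config.exact_n_max)
            s, _, _ = kendall_S(x, ref)
            p = upper_tail_p(s, s_vals, pmf)
            if best is None or p < best[0]:
                p_pairs = int(s_vals.max())
                best = (p, period, float(lag), s, p_pairs)
    p_min, period, lag, s, p_pairs = best
    tau = s / p_pairs if p_pairs else 0.0
    return JtkResult(
        series_id=series_id,
        best_period_h=period,
        best_lag_h=lag,
        phase_zt=lag % period,
        tau=float(tau),
        p_exact=float(p_min),
        p_adjusted=float(min(1.0, p_min * config.n_combinations)),
        amplitude_est=_amplitude_estimate(x, t, period, lag),
    )
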