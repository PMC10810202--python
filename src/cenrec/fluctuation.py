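"""Luria-Delbrueck fluctuation analysis.

Rates of rare mitotic events (recombination, chromosome loss) are estimated
from parallel-culture fluctuation assays: ~20 independent cultures are grown
from small inocula, the number of selectable derivatives per culture is
scored, and the expected number of events per culture ``m`` is fitted by
maximum likelihood under the Lea-Coulson formulation, using the
Ma-Sandri-Sarkar (MSS) recursion for the mutant-count pmf:

    p_0 = exp(-m),   p_k = (m / k) * sum_{j=0}^{k-1} p_j / (k - j + 1)

The per-division rate is ``m / (N_t - N_0)`` where ``N_t`` and ``N_0`` are
final and initial cells per culture.  95% confidence limits come from the
profile likelihood (log-likelihood drop of chi2_1(0.95)/2 = 1.9207).

Counts above ``CENSOR_CAP`` (10^4) are right-censored into a tail bin and
contribute a log-survival term; this bounds the O(k^2) recursion cost without
discarding jackpot cultures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CENSOR_CAP",
    "FluctuationExperiment",
    "RateEstimate",
    "SectoredRate",
    "LuriaDelbruckEstimator",
    "mss_pmf",
    "log_likelihood",
    "mle_m",
    "profile_ci",
    "estimate_rate",
    "pooled_rate",
    "sectored_colony_rate",
]

CENSOR_CAP = 10_000
_CHI2_HALF = {0.95: chi2.ppf(0.95, 1) / 2.0}  # 1.92073...


# ---------------------------------------------------------------------------
# pmf kernels
# ---------------------------------------------------------------------------

def _mss_kernel_numpy(m: float, k_max: int) -> np.ndarray:
    p = np.empty(k_max + 1)
    p[0] = math.exp(-m)
    if k_max == 0:
        return p
    # weights[j] = 1/(j+2); for step k the inner sum is dot(p[k-1::-1], weights[:k])
    weights = 1.0 / np.arange(2.0, k_max + 2.0)
    for k in range(1, k_max + 1):
        p[k] = m * np.dot(p[k - 1 :: -1], weights[:k]) / k
    return p


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    @njit(cache=False)
    def _mss_kernel_numba(m: float, k_max: int) -> np.ndarray:
        p = np.empty(k_max + 1)
        p[0] = math.exp(-m)
        for k in range(1, k_max + 1):
            s = 0.0
            for j in range(k):
                s += p[j] / (k - j + 1)
            p[k] = m * s / k
        return p

    _mss_kernel = _mss_kernel_numba
except Exception:  # pragma: no cover
    _mss_kernel = _mss_kernel_numpy


def mss_pmf(m: float, k_max: int, plating_fraction: float = 1.0) -> np.ndarray:
    """Lea-Coulson mutant-count pmf ``p_0..p_kmax`` via the MSS recursion.

    With ``plating_fraction`` e < 1 the counts are binomially thinned; the
    thinned pmf is obtained by composing the Lea-Coulson probability
    generating function with z -> 1 - e(1 - z) and inverting the series by
    FFT on the unit circle.
    """
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m}")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if not 0 < plating_fraction <= 1:
        raise ValueError("plating_fraction must be in (0, 1]")
    if m == 0:
        p = np.zeros(k_max + 1)
        p[0] = 1.0
        return p
    if plating_fraction == 1.0:
        return np.asarray(_mss_kernel(float(m), int(k_max)))
    return _thinned_pmf(float(m), int(k_max), float(plating_fraction))


def _thinned_pmf(m: float, k_max: int, e: float) -> np.ndarray:
    # series inversion of the pgf on a circle of radius r < 1; the damping
    # keeps the aliased tail below ~1e-9 while amplifying roundoff by < 20x
    n = 1 << max(8, int(np.ceil(np.log2(8 * (k_max + 1)))))
    r = 1e-9 ** (1.0 / n)
    k = np.arange(n)
    z = r * np.exp(2j * np.pi * k / n)
    t = e * (1.0 - z)  # = 1 - w where w is the thinned pgf argument
    with np.errstate(divide="ignore", invalid="ignore"):
        h = t * np.log(t) / (1.0 - t)
    h[~np.isfinite(h)] = 0.0  # limit t*log(t) -> 0 as t -> 0
    phi = np.exp(m * h)
    p = (np.fft.fft(phi).real / n) * r ** (-k.astype(float))
    return np.clip(p[: k_max + 1], 0.0, 1.0)


# ---------------------------------------------------------------------------
# likelihood and MLE
# ---------------------------------------------------------------------------

def _prep_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def log_likelihood(
    counts: Sequence[int], m: float, plating_fraction: float = 1.0
) -> float:
    """Summed log pmf of the observed counts, with right-censoring at CENSOR_CAP."""
    arr = _prep_counts(counts)
    if m == 0:
        return 0.0 if np.all(arr == 0) else -np.inf
    censored = arr > CENSOR_CAP
    observed = arr[~censored]
    k_max = int(observed.max()) if observed.size else 0
    k_max = max(k_max, 1 if censored.any() else 0)
    if censored.any():
        k_max = CENSOR_CAP
    p = mss_pmf(m, k_max, plating_fraction)
    tiny = 1e-300
    ll = float(np.log(np.maximum(p[observed], tiny)).sum())
    if censored.any():
        tail = max(1.0 - p.sum(), tiny)
        ll += int(censored.sum()) * math.log(tail)
    return ll


def mle_m(counts: Sequence[int], plating_fraction: float = 1.0) -> float:
    """Maximum-likelihood ``m`` (expected events per culture), boundary 0 allowed."""
    arr = _prep_counts(counts)
    if np.all(arr == 0):
        return 0.0

    def nll(m: float) -> float:
        return -log_likelihood(arr, m, plating_fraction)

    # crude starting scale: P0 method if zeros present, else median-based
    nz = np.count_nonzero(arr)
    if nz < arr.size:
        m0 = -math.log(1.0 - nz / arr.size + 1e-12)
    else:
        med = float(np.median(arr))
        m0 = max(med / max(math.log(max(med, 2.0)), 1.0), 0.1)
    m0 = max(m0, 1e-4)
    lo, hi = m0 / 64.0, m0 * 4.0
    while nll(hi) <= nll(hi / 2.0) and hi < 1e8:
        hi *= 4.0
    res = minimize_scalar(nll, bounds=(lo / 4.0, hi), method="bounded",
                          options={"xatol": 1e-9})
    # guard the lower boundary: likelihood may peak below the bracket
    if res.x <= lo / 2.0 and nll(lo / 8.0) < res.fun:
        res = minimize_scalar(nll, bounds=(1e-12, lo), method="bounded",
                              options={"xatol": 1e-12})
    return float(res.x)


def profile_ci(
    counts: Sequence[int],
    level: float = 0.95,
    plating_fraction: float = 1.0,
    m_hat: float | None = None,
) -> tuple[float, float]:
    """Profile-likelihood interval for ``m`` at the chi-square cutoff.

    The bounds are the values of m where the log-likelihood falls
    chi2_1(level)/2 below its maximum; the lower bound is clipped at 0.
    """
    arr = _prep_counts(counts)
    if m_hat is None:
        m_hat = mle_m(arr, plating_fraction)
    drop = _CHI2_HALF.get(level, chi2.ppf(level, 1) / 2.0)
    ll_max = log_likelihood(arr, m_hat, plating_fraction)
    target = ll_max - drop

    def f(m: float) -> float:
        return log_likelihood(arr, m, plating_fraction) - target

    # lower bound
    if m_hat == 0 or np.all(arr == 0):
        m_low = 0.0
    else:
        lo = m_hat
        while f(lo) > 0 and lo > 1e-12:
            lo /= 8.0
        m_low = 0.0 if lo <= 1e-12 else float(brentq(f, lo, m_hat, xtol=1e-12))
    # upper bound
    hi = max(m_hat * 2.0, 1e-3)
    n_expand = 0
    while f(hi) > 0 and n_expand < 60:
        hi *= 2.0
        n_expand += 1
    if f(hi) > 0:
        warnings.warn("profile likelihood upper bound did not close; "
                      "returning widest bracket", RuntimeWarning)
        m_high = hi
    else:
        m_high = float(brentq(f, max(m_hat, 1e-12), hi, xtol=1e-10))
    return m_low, m_high


# ---------------------------------------------------------------------------
# experiments and rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationExperiment:
    """Per-culture selectable counts plus the culture growth parameters.

    ``screen_fraction`` is the fraction of selected colonies confirmed as true
    events by a secondary screen (used for chromosome-loss assays where
    5-FOA resistance can also arise from recombination or point mutation).
    """

    counts: tuple[int, ...]
    n_final: float
    n_initial: float = 1.0
    plating_fraction: float = 1.0
    screen_fraction: float = 1.0
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 cultures")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if not self.n_final > self.n_initial >= 1:
            raise ValueError("require n_final > n_initial >= 1")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")
        if not 0 <= self.screen_fraction <= 1:
            raise ValueError("screen_fraction must be in [0, 1]")

    @property
    def divisions(self) -> float:
        return self.n_final - self.n_initial


@dataclass(frozen=True)
class RateEstimate:
    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    loglik_at_mle: float
    n_cultures: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("confidence limits must bracket the rate")
        if self.m_hat < 0:
            raise ValueError("m_hat must be non-negative")


def estimate_rate(
    exp: FluctuationExperiment,
    level: float = 0.95,
    with_ci: bool = True,
    thin_counts: bool = False,
    rng: np.random.Generator | None = None,
) -> RateEstimate:
    """Fit m by MSS maximum likelihood and convert to a per-division rate.

    The secondary-screen correction defaults to deterministic scaling of the
    fitted m by ``screen_fraction``; with ``thin_counts=True`` the raw counts
    are instead binomially thinned before fitting (stochastic correction).
    """
    counts = np.asarray(exp.counts, dtype=np.int64)
    sf = exp.screen_fraction
    scale = sf
    if thin_counts and sf < 1.0:
        rng = rng if rng is not None else np.random.default_rng()
        counts = rng.binomial(counts, sf)
        scale = 1.0
    m_hat = mle_m(counts, exp.plating_fraction)
    if with_ci:
        m_lo, m_hi = profile_ci(counts, level, exp.plating_fraction, m_hat=m_hat)
    else:
        m_lo = m_hi = m_hat
    ll = log_likelihood(counts, m_hat, exp.plating_fraction)
    d = exp.divisions
    return RateEstimate(
        m_hat=m_hat * scale,
        rate=m_hat * scale / d,
        ci_low=m_lo * scale / d,
        ci_high=m_hi * scale / d,
        loglik_at_mle=ll,
        n_cultures=len(exp.counts),
    )


def pooled_rate(
    experiments: Sequence[FluctuationExperiment],
    level: float = 0.95,
    with_ci: bool = True,
) -> RateEstimate:
    """Single per-division rate maximizing the summed likelihood over experiments.

    Each experiment contributes its own m = rate * divisions, so experiments
    of different culture sizes pool on the rate scale.  Heterogeneous plating
    fractions are allowed but flagged, since they make per-experiment
    likelihoods differently shaped.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    pfs = {e.plating_fraction for e in experiments}
    if len(pfs) > 1:
        warnings.warn("experiments have differing plating fractions", RuntimeWarning)
    if len(experiments) == 1:
        return estimate_rate(experiments[0], level=level, with_ci=with_ci)
    if any(e.screen_fraction != 1.0 for e in experiments):
        warnings.warn(
            "screen_fraction ignored in likelihood pooling; apply it per "
            "experiment or rescale the pooled rate", RuntimeWarning)

    arrays = [np.asarray(e.counts, dtype=np.int64) for e in experiments]

    def ll(rate: float) -> float:
        return sum(
            log_likelihood(a, rate * e.divisions, e.plating_fraction)
            for a, e in zip(arrays, experiments)
        )

    # start from the mean of per-experiment point estimates
    per = [mle_m(a, e.plating_fraction) / e.divisions
           for a, e in zip(arrays, experiments)]
    r0 = max(float(np.mean(per)), 1e-300)
    if r0 == 0 or all(np.all(a == 0) for a in arrays):
        rate_hat = 0.0
    else:
        res = minimize_scalar(lambda r: -ll(r), bounds=(r0 / 100.0, r0 * 100.0),
                              method="bounded", options={"xatol": r0 * 1e-8})
        rate_hat = float(res.x)
    ll_max = ll(rate_hat)
    if with_ci and rate_hat > 0:
        drop = _CHI2_HALF.get(level, chi2.ppf(level, 1) / 2.0)
        target = ll_max - drop

        def f(r: float) -> float:
            return ll(r) - target

        lo = rate_hat
        while f(lo) > 0 and lo > rate_hat * 1e-12:
            lo /= 8.0
        r_lo = 0.0 if lo <= rate_hat * 1e-12 else float(
            brentq(f, lo, rate_hat, xtol=rate_hat * 1e-9))
        hi = rate_hat * 2.0
        while f(hi) > 0 and hi < rate_hat * 1e12:
            hi *= 2.0
        r_hi = float(brentq(f, rate_hat, hi, xtol=rate_hat * 1e-9))
    else:
        r_lo = r_hi = rate_hat
    n = sum(len(e.counts) for e in experiments)
    mean_div = float(np.mean([e.divisions for e in experiments]))
    return RateEstimate(
        m_hat=rate_hat * mean_div,
        rate=rate_hat,
        ci_low=r_lo,
        ci_high=r_hi,
        loglik_at_mle=ll_max,
        n_cultures=n,
    )


@dataclass(frozen=True)
class SectoredRate:
    rate: float
    rate_2sf: float
    ci_low: float
    ci_high: float
    n_sectored: int
    n_total: int


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def sectored_colony_rate(n_sectored: int, n_total: int) -> SectoredRate:
    """Chromosome-loss rate from half-sectored colonies.

    A colony with similar-sized marker-plus and marker-minus sectors is taken
    as a loss event at the first division after plating, so the rate per
    division is simply the sectored fraction; a Wilson score interval is
    attached.  The point estimate is also reported to two significant figures.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_sectored <= n_total:
        raise ValueError("need 0 <= n_sectored <= n_total")
    rate = n_sectored / n_total
    lo, hi = proportion_confint(n_sectored, n_total, alpha=0.05, method="wilson")
    return SectoredRate(rate, _round_sig(rate, 2), float(lo), float(hi),
                        n_sectored, n_total)


class LuriaDelbruckEstimator(BaseEstimator):
    """Scikit-learn-style wrapper around the MSS maximum-likelihood machinery.

    Parameters
    ----------
    level : confidence level for the profile interval (default 0.95).
    with_ci : compute profile confidence limits in :meth:`fit` (default True).
    thin_counts : apply the secondary-screen correction by binomial thinning
        of the raw counts instead of deterministic scaling of m.

    After ``fit(experiment)`` the fitted attributes are ``m_``, ``rate_``,
    ``ci_low_``, ``ci_high_`` and ``estimate_`` (the full RateEstimate).
    ``fit`` also accepts a list of experiments, in which case the pooled
    likelihood over experiments is maximized.
    """

    def __init__(self, level: float = 0.95, with_ci: bool = True,
                 thin_counts: bool = False, random_state: int | None = None):
        self.level = level
        self.with_ci = with_ci
        self.thin_counts = thin_counts
        self.random_state = random_state

    def fit(self, X: FluctuationExperiment | Sequence[FluctuationExperiment],
            y=None) -> "LuriaDelbruckEstimator":
        if isinstance(X, FluctuationExperiment):
            est = estimate_rate(
                X, level=self.level, with_ci=self.with_ci,
                thin_counts=self.thin_counts,
                rng=np.random.default_rng(self.random_state),
            )
        else:
            est = pooled_rate(list(X), level=self.level, with_ci=self.with_ci)
        self.estimate_ = est
        self.m_ = est.m_hat
        self.rate_ = est.rate
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        return self

    def predict(self, X=None) -> float:
        if not hasattr(self, "rate_"):
            raise RuntimeError("estimator is not fitted")
        return self.rate_
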