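"""Interval statistics: serial correlations, Fano factor, renewal checks.

Conventions.  The serial correlation coefficient (SCC) at lag k is the
stationary-sequence estimator with a single global mean,

    rho_k = sum_i (I_i - Ibar)(I_{i+k} - Ibar) / sum_i (I_i - Ibar)^2,

so rho_0 == 1 exactly; the variance uses the population (1/n) convention.
Under the renewal null the standard error of rho_k is approximately
1/sqrt(n - k).  The long-window Fano factor of the event count obeys
F(inf) = CV^2 (1 + 2 sum_{k>=1} rho_k), and because the long-run count cannot
depend on how rotations are counted, the ISI and IPI statistics of one
trajectory must satisfy CV_ISI^2 (1 + 2 sum rho_k,ISI) = CV_IPI^2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

from .events import EventTrain, IntervalSequence


@dataclass
class IntervalSummary:
    n: int
    mean: float
    cv: float
    rate: float


@dataclass
class SerialCorrelation:
    lags: np.ndarray
    rho: np.ndarray
    se: np.ndarray

    def __getitem__(self, k: int) -> float:
        return float(self.rho[np.flatnonzero(self.lags == k)[0]])


@dataclass
class FanoCurve:
    windows: np.ndarray
    fano: np.ndarray
    asymptote: float


@dataclass
class RenewalCheckReport:
    """The Fano-factor conservation check between ISI and IPI sequences."""

    cv_isi: float
    cv_ipi: float
    scc_sum: float
    lhs: float
    rhs: float
    residual: float
    se: float
    k_max: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ShuffleTestResult:
    n_perm: int
    null_mean: float
    null_sd: float
    observed: float
    z: float


def interval_summary(seq: IntervalSequence) -> IntervalSummary:
    """Sample mean, coefficient of variation (population convention), rate."""
    x = seq.intervals
    if x.size < 2:
        raise ValueError("need at least two intervals")
    mean = float(np.mean(x))
    cv = float(np.std(x) / mean)
    return IntervalSummary(n=x.size, mean=mean, cv=cv, rate=1.0 / mean)


def scc(seq: IntervalSequence | np.ndarray, k_max: int) -> SerialCorrelation:
    """Serial correlation coefficients at lags 0..k_max.

    Global-mean stationary estimator; rho_0 == 1 exactly.  Raises on a
    degenerate (zero-variance) sequence.
    """
    x = seq.intervals if isinstance(seq, IntervalSequence) else np.asarray(seq, float)
    n = x.size
    if n <= k_max + 2:
        raise ValueError("sequence too short for the requested k_max")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("degenerate sequence: zero variance")
    lags = np.arange(k_max + 1)
    rho = np.empty(k_max + 1)
    rho[0] = 1.0
    for k in range(1, k_max + 1):
        rho[k] = float(np.dot(xc[:-k], xc[k:])) / denom
    se = np.empty(k_max + 1)
    se[0] = 0.0
    se[1:] = 1.0 / np.sqrt(n - lags[1:])
    return SerialCorrelation(lags=lags, rho=rho, se=se)


def fano_curve(train: EventTrain, windows) -> FanoCurve:
    """Fano factor var(N)/mean(N) of the count over disjoint windows.

    Requires the train to span at least 30 disjoint copies of the largest
    window; the asymptote estimate averages F over the largest windows
    (top quartile of the requested sizes).
    """
    windows = np.asarray(windows, dtype=float)
    span = train.t_end - train.t_start
    if span < 30 * windows.max():
        raise ValueError("train too short: largest window must fit >= 30 "
                         "disjoint copies")
    fano = np.empty(windows.size)
    for i, T in enumerate(windows):
        n_win = int(span / T)
        edges = train.t_start + T * np.arange(n_win + 1)
        counts = np.histogram(train.times, bins=edges)[0]
        m = counts.mean()
        fano[i] = counts.var() / m if m > 0 else np.nan
    order = np.argsort(windows)
    top = order[-max(1, windows.size // 4):]
    return FanoCurve(windows=windows, fano=fano,
                     asymptote=float(np.nanmean(fano[top])))


def _lhs_rhs(isi: np.ndarray, ipi: np.ndarray, k_max: int) -> tuple[float, float, float, float, float]:
    s_isi = scc(IntervalSequence(isi, "ISI"), k_max)
    cv_isi = float(np.std(isi) / np.mean(isi))
    cv_ipi = float(np.std(ipi) / np.mean(ipi))
    ssum = float(s_isi.rho[1:].sum())
    lhs = cv_isi**2 * (1 + 2 * ssum)
    rhs = cv_ipi**2
    return cv_isi, cv_ipi, ssum, lhs, rhs


def renewal_relation_check(isi_seq: IntervalSequence,
                           ipi_seq: IntervalSequence,
                           k_max: int = 20, n_boot: int = 1000,
                           seed: int = 0,
                           n_blocks: int = 50) -> RenewalCheckReport:
    """Check CV_ISI^2 (1 + 2 sum_k rho_k) == CV_IPI^2 on paired sequences.

    The infinite lag sum is truncated at `k_max`; the residual lhs - rhs is
    reported with a block-bootstrap standard error (whole contiguous blocks
    resampled with replacement, preserving the serial structure within
    blocks).
    """
    isi = isi_seq.intervals
    ipi = ipi_seq.intervals
    cv_isi, cv_ipi, ssum, lhs, rhs = _lhs_rhs(isi, ipi, k_max)
    rng = np.random.default_rng(seed)
    blocks_isi = np.array_split(isi, n_blocks)
    blocks_ipi = np.array_split(ipi, n_blocks)
    res = np.empty(n_boot)
    for b in range(n_boot):
        pick_i = rng.integers(0, n_blocks, size=n_blocks)
        pick_p = rng.integers(0, n_blocks, size=n_blocks)
        x = np.concatenate([blocks_isi[j] for j in pick_i])
        y = np.concatenate([blocks_ipi[j] for j in pick_p])
        _, _, _, l, r = _lhs_rhs(x, y, k_max)
        res[b] = l - r
    return RenewalCheckReport(cv_isi=cv_isi, cv_ipi=cv_ipi, scc_sum=ssum,
                              lhs=lhs, rhs=rhs, residual=lhs - rhs,
                              se=float(res.std(ddof=1)), k_max=k_max)


def shuffle_null(seq: IntervalSequence, n_perm: int = 1000,
                 seed: int = 0) -> ShuffleTestResult:
    """Shuffle test for rho_1: null distribution under random permutation.

    Permuting the intervals destroys all serial structure while preserving
    the marginal distribution; the z-score locates the observed rho_1 inside
    the permutation null.
    """
    x = seq.intervals
    if x.size < 100:
        raise ValueError("need at least 100 intervals for the shuffle test")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    observed = scc(seq, 1).rho[1]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    for p in range(n_perm):
        y = rng.permutation(xc)
        null[p] = float(np.dot(y[:-1], y[1:])) / denom
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    return ShuffleTestResult(n_perm=n_perm, null_mean=mu, null_sd=sd,
                             observed=float(observed),
                             z=float((observed - mu) / sd))


def ensemble_mean_test(rho1_values, alpha: float = 0.05):
    """One-sample t-test of zero mean over per-run rho_1 estimates.

    Returns (mean, sem, t, p, decision) with decision "reject"/"accept" at
    the given significance level.
    """
    x = np.asarray(rho1_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two runs")
    res = sps.ttest_1samp(x, 0.0)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    decision = "reject" if res.pvalue < alpha else "accept"
    return mean, sem, float(res.statistic), float(res.pvalue), decision
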