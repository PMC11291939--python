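"""Distribution fitting and hypothesis testing for xenolog count data.

The central scientific question: do xenolog subtree sizes look like a
neutral birth-death process (⇒ geometric distribution of sizes) or like
burst-driven preferential attachment (⇒ heavy-tailed Yule–Simon law,
f(k; α) = α·B(k, α+1))?  This module provides the pieces needed to ask it:

* the Yule–Simon pmf and a numeric ML estimator for α;
* maximum-likelihood geometric fitting, plain (p̂ = 1/mean) and truncated
  to a support window (score equation solved numerically);
* a Pearson chi-square goodness-of-fit with expected-count pooling, in a
  model-based mode and an empirical-background-as-expected mode;
* a permutation Spearman correlation test;
* the zero-intercept Poisson-ish regression of intron count on branch
  distance to the subtree root (the intronization rate, introns per
  substitution per site).

Geometric convention throughout: pmf p(1-p)^(k-1) on k ≥ 1, so the
parameter is the per-trial success probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats as sps


@dataclass
class BinningRecord:
    """Audit trail of chi-square binning: pooled bin edges and counts."""

    bin_values: list[list[int]]        # raw support values pooled per bin
    observed: list[float]
    expected: list[float]


@dataclass
class DistributionFit:
    family: str                        # "geometric" | "yule_simon"
    parameter: float
    support: tuple[int, int] | None
    statistic: float | None = None
    df: int | None = None
    pvalue: float | None = None
    binning: BinningRecord | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class RegressionFit:
    slope: float
    n: int
    tstat: float
    pvalue: float


# -- Yule-Simon ------------------------------------------------------------


def yule_simon_pmf(k, alpha: float):
    """P(K = k) = α·B(k, α+1) for k ≥ 1; for α = 1 this is 1/(k(k+1))."""
    k = np.asarray(k)
    if np.any(k < 1) or not np.all(k == np.floor(k)):
        raise ValueError("Yule-Simon support is the positive integers")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = alpha * special.beta(k, alpha + 1.0)
    return out if out.shape else float(out)


def fit_yule_simon_ml(sample, support: tuple[int, int] | None = None) -> DistributionFit:
    """Numeric ML estimate of α (optionally truncated-renormalized)."""
    x = np.asarray(sample, dtype=int)
    if x.size == 0:
        raise ValueError("empty sample")
    if support is not None:
        lo, hi = support
        x = x[(x >= lo) & (x <= hi)]
        ks = np.arange(lo, hi + 1)

    def negll(alpha: float) -> float:
        if support is None:
            return -float(np.sum(np.log(alpha * special.beta(x, alpha + 1.0))))
        pm = alpha * special.beta(ks, alpha + 1.0)
        pm = pm / pm.sum()
        return -float(np.sum(np.log(pm[x - lo])))

    res = optimize.minimize_scalar(negll, bounds=(1e-6, 100.0), method="bounded")
    return DistributionFit(family="yule_simon", parameter=float(res.x), support=support)


# -- geometric -------------------------------------------------------------


def fit_geometric_ml(
    sample, support: tuple[int, int] | None = None, truncated: bool = False
) -> DistributionFit:
    """ML fit of Geometric(p), pmf p(1-p)^(k-1) on k ≥ 1.

    Untruncated: p̂ = 1/mean.  Truncated: values outside ``support`` are a
    precondition violation; the likelihood of the window-renormalized pmf
    is maximized numerically.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    fit = DistributionFit(family="geometric", parameter=np.nan, support=support)
    if not truncated:
        m = x.mean()
        if m <= 1.0:
            fit.parameter = 1.0
            fit.warnings.append("sample mean ≤ 1: p̂ clamped to the boundary 1.0")
        else:
            fit.parameter = 1.0 / m
        return fit
    if support is None:
        raise ValueError("truncated fit requires a support window")
    lo, hi = support
    if np.any((x < lo) | (x > hi)):
        raise ValueError("sample values outside the truncation window")
    ks = np.arange(lo, hi + 1, dtype=float)

    def negll(p: float) -> float:
        logpm = np.log(p) + (ks - 1.0) * np.log1p(-p)
        logpm -= special.logsumexp(logpm)
        return -float(np.sum(logpm[(x - lo).astype(int)]))

    res = optimize.minimize_scalar(negll, bounds=(1e-9, 1 - 1e-9), method="bounded")
    fit.parameter = float(res.x)
    return fit


# -- goodness of fit -------------------------------------------------------


def _pool_bins(
    values: np.ndarray, observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> BinningRecord:
    """Pool adjacent support values (low end upward) until expected ≥ min_expected."""
    bins, obs, exp = [], [], []
    cur_v: list[int] = []
    cur_o = cur_e = 0.0
    for v, o, e in zip(values, observed, expected):
        cur_v.append(int(v))
        cur_o += o
        cur_e += e
        if cur_e >= min_expected:
            bins.append(cur_v)
            obs.append(cur_o)
            exp.append(cur_e)
            cur_v, cur_o, cur_e = [], 0.0, 0.0
    if cur_v:
        if bins:
            bins[-1].extend(cur_v)
            obs[-1] += cur_o
            exp[-1] += cur_e
        else:
            bins, obs, exp = [cur_v], [cur_o], [cur_e]
    return BinningRecord(bins, obs, exp)


def chisq_gof(
    sample,
    family: str,
    parameter: float,
    support: tuple[int, int],
    ddof: int = 0,
    min_expected: float = 5.0,
) -> DistributionFit:
    """Pearson chi-square GOF of a sample against a (renormalized) model.

    Expected counts are the window-renormalized pmf of ``family`` at
    ``parameter`` times the sample size; bins with expected below
    ``min_expected`` are pooled; df = #bins − 1 − ddof (pass ddof=1 when
    the parameter was estimated from the same sample).
    """
    x = np.asarray(sample, dtype=int)
    lo, hi = support
    x = x[(x >= lo) & (x <= hi)]
    if x.size == 0:
        raise ValueError("no sample values in the support window")
    ks = np.arange(lo, hi + 1)
    if family == "geometric":
        pm = parameter * (1 - parameter) ** (ks - 1)
    elif family == "yule_simon":
        pm = yule_simon_pmf(ks, parameter)
    else:
        raise ValueError(f"unknown family {family!r}")
    pm = pm / pm.sum()
    observed = np.bincount(x, minlength=hi + 1)[lo : hi + 1].astype(float)
    expected = pm * x.size
    rec = _pool_bins(ks, observed, expected, min_expected)
    if len(rec.observed) < 2:
        raise ValueError("fewer than 2 bins after pooling; cannot test")
    stat = float(np.sum((np.array(rec.observed) - np.array(rec.expected)) ** 2
                        / np.array(rec.expected)))
    df = len(rec.observed) - 1 - ddof
    p = float(sps.chi2.sf(stat, df))
    return DistributionFit(
        family=family, parameter=parameter, support=support,
        statistic=stat, df=df, pvalue=p, binning=rec,
    )


def chisq_vs_background(
    observed, background, ddof: int = 0, min_expected: float = 5.0
) -> tuple[float, int, float]:
    """Chi-square with an empirical background as the expected distribution.

    ``observed`` and ``background`` are category counts over the same bins;
    the background is rescaled to the observed total.  Bins with expected
    below ``min_expected`` are pooled from the low end.
    """
    obs = np.asarray(observed, dtype=float)
    bg = np.asarray(background, dtype=float)
    if obs.shape != bg.shape:
        raise ValueError("observed and background must share categories")
    exp = bg / bg.sum() * obs.sum()
    rec = _pool_bins(np.arange(obs.size), obs, exp, min_expected)
    if len(rec.observed) < 2:
        raise ValueError("fewer than 2 bins after pooling; cannot test")
    stat = float(np.sum((np.array(rec.observed) - np.array(rec.expected)) ** 2
                        / np.array(rec.expected)))
    df = len(rec.observed) - 1 - ddof
    return stat, df, float(sps.chi2.sf(stat, df))


# -- permutation Spearman --------------------------------------------------


def perm_spearman(
    x, y, n_perm: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test of Spearman's rho.

    p = (1 + #{permutations with |rho*| ≥ |rho|}) / (1 + n_perm); the
    smallest achievable p is therefore 1/(n_perm + 1) — extreme claims are
    floors, not exact values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(rx @ ry / n)
    rng = np.random.default_rng(seed)
    exceed = 0
    block = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(ry, (b, 1)), axis=1)
        rho_star = perms @ rx / n
        exceed += int(np.sum(np.abs(rho_star) >= abs(rho) - 1e-12))
        done += b
    p = (1 + exceed) / (1 + n_perm)
    return rho, float(p)


# -- intronization regression ---------------------------------------------


def fit_intronization(introns, dist_to_root) -> RegressionFit:
    """Zero-intercept least squares of intron count on branch distance.

    β̂ = Σxy/Σx² (introns per substitution per site); the p-value is the
    usual t test of the no-intercept model with n − 1 residual df.
    """
    y = np.asarray(introns, dtype=float)
    x = np.asarray(dist_to_root, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("introns and distances must be equal-length and nonempty")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("distances and counts must be nonnegative")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all distances are zero; slope undefined")
    beta = float(np.sum(x * y) / sxx)
    n = x.size
    resid = y - beta * x
    if n > 1:
        s2 = float(np.sum(resid**2)) / (n - 1)
        se = np.sqrt(s2 / sxx)
        t = beta / se if se > 0 else np.inf
        p = float(2 * sps.t.sf(abs(t), n - 1))
    else:
        t, p = np.inf, np.nan
    return RegressionFit(slope=beta, n=n, tstat=float(t), pvalue=p)
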