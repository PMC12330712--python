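"""Inferential statistics: t-tests with paired-design effect sizes, JZS
default-prior Bayes factors, and (partial) Spearman rank correlations.

The Bayes factor follows the Zellner-Siow construction for one-sample and
paired designs: a Cauchy prior with scale r on the standardized effect,
expressed as a normal-on-effect mixed over g ~ inverse-gamma(1/2, r^2/2),
integrated numerically. For one-sample and paired designs Cohen's d is
t / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior_scale: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    kind: str  # "spearman" | "partial_spearman"
    control_variable: str | None = None


def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    """Classical one-sample t against mu0 with d = (mean - mu0)/sd = t/sqrt(n)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        if np.allclose(x, mu0):
            # degenerate but well-defined: no deviation from the null at all
            return TTestResult(t=0.0, df=n - 1, p=1.0, d=0.0,
                               mean=float(mu0), se=0.0, n=n)
        raise ValueError("zero variance: t-test undefined")
    mean = float(x.mean())
    se = float(sd / math.sqrt(n))
    t = (mean - mu0) / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p), d=float(t / math.sqrt(n)),
                       mean=mean, se=se, n=n)


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired t-test: one-sample t on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


def jzs_bf(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """JZS Bayes factor for a one-sample/paired t statistic.

    BF10 = E_g[(1+Ng)^(-1/2) ((1 + t^2/((1+Ng) nu)) / (1 + t^2/nu))^(-(nu+1)/2)]
    with nu = n - 1 and g ~ inverse-gamma(1/2, prior_scale^2 / 2). The
    likelihood ratio is folded into the expectation so the integrand stays
    bounded for large |t|. Raises if the quadrature does not converge to the
    requested relative tolerance; there is no silent fallback.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be > 0")
    nu = n - 1
    a = 0.5
    b = prior_scale * prior_scale / 2.0
    t2 = float(t) * float(t)

    def integrand(g):
        log_prior = a * math.log(b) - special.gammaln(a) - (a + 1.0) * np.log(g) - b / g
        log_ratio = (-0.5 * np.log1p(n * g)
                     - 0.5 * (nu + 1) * (np.log1p(t2 / ((1.0 + n * g) * nu))
                                         - np.log1p(t2 / nu)))
        return np.exp(log_prior + log_ratio)

    val, abserr = integrate.quad(integrand, 0.0, np.inf,
                                 epsabs=0.0, epsrel=1e-10, limit=300)
    if not np.isfinite(val) or val <= 0.0 or abserr > 1e-6 * val:
        raise RuntimeError(
            f"JZS quadrature did not converge (value {val}, abserr {abserr})")
    return BayesFactorResult(bf10=float(val), prior_scale=float(prior_scale))


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ties), p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input: correlation undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue),
                             n=n, kind="spearman")


def partial_spearman_rho(x, y, z, control_name: str = "z") -> CorrelationResult:
    """First-order partial Spearman correlation of x and y controlling z.

    Ranks all three with average ties, then
    (rho_xy - rho_xz rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2)),
    with the p-value from the t approximation at df = n - 3.
    """
    arrs = [np.asarray(v, dtype=float) for v in (x, y, z)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("inputs must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx, ry, rz = (stats.rankdata(a) for a in arrs)
    cm = np.corrcoef(np.vstack([rx, ry, rz]))
    r_xy, r_xz, r_yz = cm[0, 1], cm[0, 2], cm[1, 2]
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:
        raise ValueError("degenerate control: |rho_xz| or |rho_yz| is 1")
    rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tval = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(tval), df)
    return CorrelationResult(rho=rho, p=float(p), n=n,
                             kind="partial_spearman", control_variable=control_name)
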