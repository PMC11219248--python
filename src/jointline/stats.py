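"""Cohort statistics: summaries, Pearson correlation, ICC, and the power
of the correlation test.

Everything here is computed from first principles on top of scipy's
distribution functions:

* :func:`summarize` — sample mean, SD (n-1 denominator) and the Student-t
  95% confidence interval of the mean.
* :func:`pearson` — product-moment correlation with the two-sided p-value
  from ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom.
* :func:`icc_absolute_agreement` — ICC(2,1): two-way random effects,
  absolute agreement, single rater, from the ANOVA mean squares.
* :func:`correlation_power` — power of the test that a population
  correlation is zero, either via the exact sampling density of r under a
  bivariate-normal population (the default; this is what dedicated power
  software computes) or via the Fisher-z normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats as sps

__all__ = [
    "SummaryStat",
    "CorrelationResult",
    "ICCResult",
    "PowerSpec",
    "InsufficientDataError",
    "ZeroVarianceError",
    "MissingDataError",
    "summarize",
    "pearson",
    "icc_absolute_agreement",
    "correlation_power",
    "sample_correlation_pdf",
    "critical_r",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant variable."""


class MissingDataError(ValueError):
    """The ratings matrix contains missing cells."""


@dataclass(frozen=True)
class SummaryStat:
    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float

    def display(self, decimals: int = 1) -> str:
        """Rounded rendering, half away from zero (e.g. ``29.4 ± 2.2 (29.0 to 29.7)``)."""

        def r(x):
            q = 10.0**decimals
            return np.sign(x) * np.floor(abs(x) * q + 0.5) / q

        return (
            f"{r(self.mean):.{decimals}f} ± {r(self.sd):.{decimals}f} "
            f"(95% CI: {r(self.ci95_low):.{decimals}f} to {r(self.ci95_high):.{decimals}f})"
        )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class PowerSpec:
    rho: float
    alpha: float = 0.05
    n: int = 127
    tails: str = "two"
    method: str = "exact"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.method not in ("fisher_z", "exact", "nct"):
            raise ValueError("method must be 'fisher_z', 'exact' or 'nct'")


def summarize(values) -> SummaryStat:
    """Sample mean, SD and the t-based 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("summarize needs at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return SummaryStat(n=n, mean=mean, sd=sd, ci95_low=mean - half, ci95_high=mean + half)


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("pearson needs at least 3 pairs")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd**2))
    sy = np.sqrt(np.sum(yd**2))
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation undefined for a constant variable")
    r = float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p_two_sided=p, n=n)


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a (subjects x raters) matrix with no missing cells.  With
    MSR/MSC/MSE the subject, rater and residual mean squares of the two-way
    ANOVA decomposition::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise InsufficientDataError("ICC needs >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise MissingDataError("ratings matrix contains missing/non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return ICCResult(
        icc=icc,
        model="two-way random, absolute agreement, single rater (ICC(2,1))",
        n_subjects=n,
        n_raters=k,
    )


def sample_correlation_pdf(r, rho: float, n: int):
    """Exact density of the sample correlation coefficient.

    For ``n`` observations from a bivariate normal population with
    correlation ``rho`` (Hotelling's form, evaluated in log space with a
    Gaussian hypergeometric factor)::

        f(r) = (n-2) G(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
               / (sqrt(2 pi) G(n-1/2) (1-rho r)^(n-3/2))
               * 2F1(1/2, 1/2; n-1/2; (1+rho r)/2)
    """
    r = np.asarray(r, dtype=float)
    log_c = (
        np.log(n - 2.0)
        + special.gammaln(n - 1.0)
        - 0.5 * np.log(2.0 * np.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 1.0) * np.log1p(-(rho**2))
    )
    with np.errstate(divide="ignore"):
        log_body = 0.5 * (n - 4.0) * np.log1p(-(r**2)) - (n - 1.5) * np.log1p(-rho * r)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1.0 + rho * r))
    return np.exp(log_c + log_body) * hyp


def critical_r(alpha: float, n: int, tails: str = "two") -> float:
    """Rejection threshold on |r| for the t-test of zero correlation."""
    a = alpha / 2.0 if tails == "two" else alpha
    t_c = float(sps.t.ppf(1.0 - a, n - 2))
    return t_c / np.sqrt(n - 2.0 + t_c**2)


def _tail_prob(rho: float, n: int, lo: float, hi: float) -> float:
    val, _ = integrate.quad(sample_correlation_pdf, lo, hi, args=(rho, n), limit=200)
    return val


def correlation_power(spec: PowerSpec) -> float:
    """Power of the null-correlation test against a true correlation ``rho``.

    ``exact`` integrates the exact bivariate-normal sampling density of r
    beyond the critical r of the t-test; ``fisher_z`` uses the normal
    approximation ``atanh(r) ~ N(atanh(rho), 1/(n-3))``; ``nct`` is the
    point-biserial-style noncentral-t approximation used by some power
    software (noncentrality ``rho sqrt(n) / sqrt(1 - rho^2)``), which runs
    slightly anticonservative for a truly bivariate-normal population.
    """
    rho, alpha, n = spec.rho, spec.alpha, spec.n
    r_c = critical_r(alpha, n, spec.tails)
    if spec.method == "exact":
        # one-tailed: reject in the direction of the alternative
        if spec.tails == "one":
            if rho >= 0:
                return _tail_prob(rho, n, r_c, 1.0)
            return _tail_prob(rho, n, -1.0, -r_c)
        return _tail_prob(rho, n, r_c, 1.0) + _tail_prob(rho, n, -1.0, -r_c)

    if spec.method == "nct":
        delta = rho * np.sqrt(n) / np.sqrt(1.0 - rho**2)
        df = n - 2
        if spec.tails == "one":
            t_c = float(sps.t.ppf(1.0 - alpha, df))
            return float(sps.nct.sf(t_c, df, abs(delta)))
        t_c = float(sps.t.ppf(1.0 - alpha / 2.0, df))
        return float(sps.nct.sf(t_c, df, delta) + sps.nct.cdf(-t_c, df, delta))

    zeta = np.arctanh(rho) * np.sqrt(n - 3.0)
    if spec.tails == "one":
        z_c = float(sps.norm.ppf(1.0 - alpha))
        return float(sps.norm.cdf(abs(zeta) - z_c))
    z_c = float(sps.norm.ppf(1.0 - alpha / 2.0))
    return float(sps.norm.cdf(zeta - z_c) + sps.norm.cdf(-zeta - z_c))
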