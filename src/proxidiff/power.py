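"""Two-sample power analysis parameterized by CV and fold change.

Answers the design question "how many replicates per group detect an
f-fold enrichment at replicate CV c with two-sided level alpha?" for the
two-independent-means t-test, using the exact noncentral-t power (no normal
approximation — the group sizes of interest are small).

Two effect-size conventions are supported for turning (CV, fold change)
into Cohen's d:

``lognormal`` (default)
    Intensities are treated as lognormal, as the pipeline's log2 transform
    assumes.  The within-group SD on the log2 scale is
    sigma = sqrt(ln(1 + cv^2)) / ln 2 and the effect is delta = log2(fc),
    giving d = log2(fc) / sigma.

``raw``
    Means and SD on the raw scale: the two group means are 1 and fc, the
    common SD is cv times their average, giving
    d = (fc - 1) / (cv * (1 + fc) / 2).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "cohens_d_from_cv_fc",
    "power_two_sample",
    "min_n_for_power",
    "simulate_power",
]

_CONVENTIONS = ("lognormal", "raw")


def cohens_d_from_cv_fc(cv: float, fold_change: float, convention: str = "lognormal") -> float:
    """Standardized effect size implied by a replicate CV and a fold change."""
    if fold_change < 1.0:
        raise ValueError("fold_change must be >= 1 (use the reciprocal for depletion)")
    if cv <= 0.0:
        raise ValueError("cv must be positive")
    if convention == "lognormal":
        sigma_log2 = math.sqrt(math.log1p(cv**2)) / math.log(2.0)
        return math.log2(fold_change) / sigma_log2
    if convention == "raw":
        return (fold_change - 1.0) / (cv * (1.0 + fold_change) / 2.0)
    raise ValueError(f"unknown convention {convention!r}; choose from {_CONVENTIONS}")


def power_two_sample(
    n_per_group: int,
    cv: float,
    fold_change: float,
    alpha: float = 0.05,
    convention: str = "lognormal",
) -> float:
    """Exact power of the two-sided two-independent-means t-test.

    With d = Cohen's d, noncentrality lambda = d*sqrt(n/2) and df = 2n - 2,
    power = P(|T'| > t_{1-alpha/2, df}) under the noncentral t.  At
    fold_change = 1 this reduces to the size of the test (alpha).
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError("n_per_group must be at least 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    d = cohens_d_from_cv_fc(cv, fold_change, convention)
    df = 2 * n - 2
    lam = d * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, lam) + stats.nct.cdf(-tcrit, df, lam))


def min_n_for_power(
    target_power: float,
    cv: float,
    fold_change: float,
    alpha: float = 0.05,
    convention: str = "lognormal",
) -> int:
    """Smallest group size n >= 2 reaching the target power (doubling + bisection)."""
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    if power_two_sample(2, cv, fold_change, alpha, convention) >= target_power:
        return 2
    lo, hi = 2, 4
    while power_two_sample(hi, cv, fold_change, alpha, convention) < target_power:
        lo, hi = hi, hi * 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_two_sample(mid, cv, fold_change, alpha, convention) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def simulate_power(
    n_per_group: int,
    cv: float,
    fold_change: float,
    alpha: float = 0.05,
    n_reps: int = 50_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Welch test under the lognormal intensity model.

    Simulates n_reps independent experiments: log2 intensities are normal
    with SD sqrt(ln(1 + cv^2))/ln 2, the bait group shifted by log2(fc),
    and each experiment is analyzed with Welch's t-test.  Serves as an
    independent check on the noncentral-t computation.
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2)) / math.log(2.0)
    delta = math.log2(fold_change)
    x = rng.normal(delta, sigma, size=(n_reps, n))
    y = rng.normal(0.0, sigma, size=(n_reps, n))
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / n + vy / n
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / n) ** 2 / (n - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return float((p < alpha).mean())
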