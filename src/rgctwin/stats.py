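"""Statistical procedures: permutation test, bootstrap CIs, effect sizes.

These are the four procedures used to compare detection performance between
cell groups: a two-sample permutation test on |mean difference| with
100,000 label shuffles, percentile bootstrap confidence intervals from 100
resamples, Cohen's d with the pooled SD, and Pearson correlation, plus the
Bonferroni correction used for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PermutationResult:
    observed: float
    p_value: float  # printed rule: proportion of null strictly larger
    p_value_safe: float  # (k+1)/(n+1) finite-sample-safe variant
    n_perm: int
    null_samples: np.ndarray
    seed: int | None


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    n_boot: int
    seed: int | None


def permutation_test(
    a,
    b,
    n_perm: int = 100_000,
    seed: int | None = None,
    min_group: int = 4,
    keep_null: bool = False,
) -> PermutationResult:
    """Two-sample permutation test on the absolute mean difference.

    The p-value follows the strict rule (proportion of shuffled statistics
    larger than the observed one); when the observed statistic is exactly 0
    that rule is degenerate and the p-value is reported as 1.  The
    finite-sample-safe (k+1)/(n+1) variant is always reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < min_group or len(b) < min_group:
        raise ValueError(
            f"groups must each have at least N={min_group} members "
            f"(got {len(a)} and {len(b)})"
        )
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    rng = np.random.default_rng(seed)
    # vectorised shuffles: one permuted index matrix
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[idx]
    null = np.abs(
        shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    )
    # numerically-equal shuffled statistics are ties, not exceedances
    tol = 1e-9 * max(1.0, abs(observed))
    k_strict = int(np.sum(null > observed + tol))
    k_ge = int(np.sum(null >= observed - tol))
    p = 1.0 if observed == 0 else k_strict / n_perm
    p_safe = (k_ge + 1) / (n_perm + 1)
    return PermutationResult(
        observed=float(observed),
        p_value=float(p),
        p_value_safe=float(p_safe),
        n_perm=n_perm,
        null_samples=null if keep_null else np.empty(0),
        seed=seed,
    )


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 100,
    seed: int | None = None,
    ci: float = 95.0,
) -> BootstrapCI:
    """Percentile bootstrap CI for ``statistic`` of a sample.

    ``values`` may also be a tuple of two samples, in which case
    ``statistic(a, b)`` is computed on independent resamples of each (the
    form used for group differences in AUC).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    if isinstance(values, tuple):
        a, b = (np.asarray(v, dtype=float) for v in values)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs n >= 2")
        est = float(statistic(a, b))
        boots = np.array(
            [
                statistic(
                    a[rng.integers(0, len(a), len(a))],
                    b[rng.integers(0, len(b), len(b))],
                )
                for _ in range(n_boot)
            ]
        )
    else:
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError("need n >= 2")
        est = float(statistic(v))
        boots = np.array(
            [statistic(v[rng.integers(0, len(v), len(v))]) for _ in range(n_boot)]
        )
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [half, 100.0 - half])
    return BootstrapCI(estimate=est, lower=float(lo), upper=float(hi),
                       n_boot=n_boot, seed=seed)


def cohens_d(a, b) -> float:
    """|mean difference| over the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float(abs(a.mean() - b.mean()) / pooled)


def pearson(x, y, flag_constant: bool = True) -> float:
    """Pearson correlation coefficient; constant input is flagged as 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    xd, yd = x - x.mean(), y - y.mean()
    den = np.sqrt((xd**2).sum() * (yd**2).sum())
    if den == 0:
        if flag_constant:
            import warnings

            warnings.warn("constant input to pearson; returning 0")
        return 0.0
    return float((xd * yd).sum() / den)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance level, rounded to 4 decimals."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 4)
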