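"""Group statistics: rank-sum tests, bootstrap SEMs, z-comparisons, ΔΔCt.

The cohort comparisons use the two-sample Wilcoxon rank-sum
(Mann–Whitney) test on per-recording summaries — exact by enumeration
for small tie-free samples, normal approximation with tie correction
otherwise — and, for pooled per-event statistics, bootstrap resampling
of the mean (10,000 resamples) whose Gaussian-fitted spread estimates
the standard error of each group mean; group differences are then
expressed as z-scores.  qPCR cycle-threshold tables are converted to
fold changes by the comparative Ct (ΔΔCt) method with a square-root
variance-stabilizing transform; downstream ANOVA/Tukey are ordinary
library routines operating on the transformed folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "BootstrapResult",
    "GroupComparison",
    "ranksum_test",
    "signed_rank_test",
    "bootstrap_mean",
    "bootstrap_z_comparison",
    "compare_groups",
    "ddct_fold_change",
]

#: Enumeration is abandoned above this many rank assignments.
_MAX_ENUMERATION = 2_000_000


def ranksum_test(
    a: Sequence[float],
    b: Sequence[float],
    exact_max_n: int = 10,
) -> Tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    When the smaller sample has at most ``exact_max_n`` observations,
    there are no ties, and the number of rank assignments is manageable,
    the p-value is exact: the fraction of all C(n_a+n_b, n_a) rank
    assignments whose rank-sum deviates from its null mean by at least
    the observed amount (the null is symmetric, so this equals doubling
    the smaller tail).  Otherwise the normal approximation with tie
    correction and continuity correction is used.

    Returns ``(rank_sum_of_a, p_two_sided)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    n_small = min(a.size, b.size)
    n_total = a.size + b.size
    if (
        not has_ties
        and n_small <= exact_max_n
        and comb(n_total, a.size) <= _MAX_ENUMERATION
    ):
        p = _exact_ranksum_p(ranks.astype(int), a.size, w_obs)
        return w_obs, p
    _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w_obs, float(p)


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided p by full enumeration of rank assignments."""
    n = ranks.size
    mean_w = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for idx in combinations(range(1, n + 1), n_a):
        total += 1
        if abs(sum(idx) - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def signed_rank_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Paired Wilcoxon signed-rank test (provided for completeness).

    The cohort pipeline compares independent groups and uses
    :func:`ranksum_test`; this paired variant exists for within-recording
    contrasts.
    """
    res = sps.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class BootstrapResult:
    """Bootstrap distribution of a sample mean."""

    n_resamples: int
    resampled_means: np.ndarray
    mean_of_means: float
    sem_gaussian_fit: float  # ML Gaussian fit to the resampled means
    sem_empirical_sd: float  # sample SD of the resampled means
    sem_histogram_fit: float  # Gaussian fitted to the binned density
    seed: int


def bootstrap_mean(
    data: Sequence[float], n_resamples: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap the mean: resample with replacement at original size.

    The spread of the resampled means estimates the standard error of
    the mean.  Two Gaussian fits of the probability density are
    reported: the maximum-likelihood fit (whose σ is the SD of the
    resampled means) and a least-squares Gaussian fit to the binned
    density; they agree closely for unimodal data.
    """
    data = np.asarray(data, dtype=float)
    n = data.size
    if n < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = data[idx].mean(axis=1)
    mle_sigma = float(means.std(ddof=0))
    emp_sd = float(means.std(ddof=1))
    hist_sigma = _histogram_gaussian_sigma(means, fallback=mle_sigma)
    return BootstrapResult(
        n_resamples=n_resamples,
        resampled_means=means,
        mean_of_means=float(means.mean()),
        sem_gaussian_fit=mle_sigma,
        sem_empirical_sd=emp_sd,
        sem_histogram_fit=hist_sigma,
        seed=seed,
    )


def _histogram_gaussian_sigma(means: np.ndarray, fallback: float) -> float:
    if means.std() == 0:
        return 0.0
    density, edges = np.histogram(means, bins=50, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sigma):
        return np.exp(-((x - mu) ** 2) / (2 * sigma**2)) / (
            sigma * np.sqrt(2 * np.pi)
        )

    try:
        popt, _ = curve_fit(
            gauss, centers, density, p0=(means.mean(), means.std() or 1.0)
        )
        return float(abs(popt[1]))
    except RuntimeError:
        return fallback


def bootstrap_z_comparison(
    res_a: BootstrapResult, res_b: BootstrapResult
) -> Tuple[float, float]:
    """z-score for the difference of two bootstrapped group means.

    ``z = (mean_a − mean_b) / sqrt(sem_a² + sem_b²)`` with the
    Gaussian-fit SEMs; two-sided p from the standard normal.
    """
    sa, sb = res_a.sem_gaussian_fit, res_b.sem_gaussian_fit
    if sa == 0 and sb == 0:
        raise ValueError("both SEMs are zero; z-score undefined")
    z = (res_a.mean_of_means - res_b.mean_of_means) / sqrt(sa**2 + sb**2)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    return float(z), float(p)


@dataclass
class GroupComparison:
    """One metric compared between two groups."""

    statistic_name: str
    group_a: np.ndarray
    group_b: np.ndarray
    rank_sum_a: float
    p_ranksum: float
    z_score_bootstrap: float
    p_z_two_sided: float
    n_resamples: int
    seed: int


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    statistic_name: str = "metric",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Rank-sum plus bootstrap-z comparison of one metric between groups."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    w, p_rs = ranksum_test(a, b)
    res_a = bootstrap_mean(a, n_resamples, seed=seed)
    res_b = bootstrap_mean(b, n_resamples, seed=seed + 1)
    z, p_z = bootstrap_z_comparison(res_a, res_b)
    return GroupComparison(
        statistic_name=statistic_name,
        group_a=a,
        group_b=b,
        rank_sum_a=w,
        p_ranksum=p_rs,
        z_score_bootstrap=z,
        p_z_two_sided=p_z,
        n_resamples=n_resamples,
        seed=seed,
    )


def ddct_fold_change(
    ct_table: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Comparative-Ct fold changes with square-root transform.

    ``ct_table`` columns: ``sample``, ``group``, ``gene``,
    ``reference_gene``, ``ct``, ``ct_ref``.  Per row
    ``ΔCt = ct − ct_ref``; per gene ``ΔΔCt = ΔCt − mean ΔCt`` of the
    control group; ``fold = 2^(−ΔΔCt)``; ``sqrt_fold`` is the
    variance-stabilized value handed to ANOVA/Tukey.
    """
    required = {"sample", "group", "gene", "reference_gene", "ct", "ct_ref"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table is missing columns: {sorted(missing)}")
    df = ct_table.copy()
    bad = df[df["ct_ref"].isna() | df["ct"].isna()]
    if len(bad):
        raise ValueError(
            "missing Ct values for samples: "
            + ", ".join(map(str, bad["sample"].tolist()))
        )
    df["delta_ct"] = df["ct"] - df["ct_ref"]
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        control = sub[sub["group"] == control_group]
        if control.empty:
            raise ValueError(
                f"control group {control_group!r} has no samples for "
                f"gene {gene!r}"
            )
        ref = control["delta_ct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["delta_ct"] - ref
        sub["fold_change"] = 2.0 ** (-sub["ddct"])
        sub["sqrt_fold_change"] = np.sqrt(sub["fold_change"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)
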