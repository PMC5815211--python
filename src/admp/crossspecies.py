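"""Comparative analyses of methylation-ageing rates.

The comparisons operate on gradients — per-site or per-region fitted
slopes of methylation on age, in fraction per week — and ask how their
magnitudes relate to lifespan: across species (rank correlation of the
mean negative-log gradient with maximum lifespan T_max), between breeds
of one species (rank-sum test on shared regions), and between the same
chromosome ageing in two cellular contexts (paired-gradient regression
and ratio summaries).

The headline inferences in this layer use exact small-sample
nonparametric tests: the Spearman p-value is computed by full
enumeration of rank permutations and the Wilcoxon rank-sum p-value by
count convolution over rank-sum arrangements, with large-sample
approximations (flagged in the result) only beyond the exact regimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("admp.crossspecies")

RATIO_FLOOR = 1e-6  # fraction/week; |gradient_a| below this cannot divide


def neg_log_gradient(gradient: float | np.ndarray) -> float | np.ndarray:
    """-log10 of the gradient magnitude; larger = slower epigenetic ageing."""
    g = np.abs(np.asarray(gradient, dtype=float))
    if (g == 0).any():
        raise ValueError("zero gradient has no defined rate; exclude upstream")
    out = -np.log10(g)
    return float(out) if np.isscalar(gradient) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# exact nonparametric tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def spearman_exact(x: Sequence[float], y: Sequence[float], exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is computed from average ranks.  For n <= ``exact_max_n`` with
    no ties on either side, the two-sided p is exact: the fraction of
    all n! rank pairings whose |rho| is at least |rho_observed|.
    Otherwise the large-sample t approximation is used and flagged
    (only approximate in the presence of ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    ties = len(set(x)) < n or len(set(y)) < n
    if n <= exact_max_n and not ties:
        # no ties: rho_perm = 1 - 6*sum(d^2)/(n(n^2-1))
        denom = n * (n * n - 1)
        count = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            d = rx - np.asarray(perm)
            rho_perm = 1.0 - 6.0 * float(d @ d) / denom
            if abs(rho_perm) >= target:
                count += 1
        p = count / _factorial(n)
        return TestResult(rho, p, "exact-permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    method = "t-approximation (ties present)" if ties else "t-approximation"
    return TestResult(rho, p, method)


def _factorial(n: int) -> int:
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


def _ranksum_counts(n_total: int, m: int) -> np.ndarray:
    """counts[s] = number of m-subsets of ranks 1..n_total summing to s."""
    max_sum = m * n_total
    # dp[k][s]: subsets of size k with sum s
    dp = np.zeros((m + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for rank in range(1, n_total + 1):
        for k in range(min(m, rank), 0, -1):
            dp[k, rank:] += dp[k - 1, : max_sum + 1 - rank]
    return dp[m]


def ranksum_exact(x: Sequence[float], y: Sequence[float], exact_max_total: int = 20) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, exact for small samples.

    The statistic is W, the rank sum of ``x`` in the pooled sample.  For
    m + n <= ``exact_max_total`` with no ties, the two-sided p is exact:
    the probability, over all C(m+n, m) equally likely rank assignments,
    of a rank sum at least as far from its mean as observed.  Otherwise
    the normal approximation with tie correction is used (delegated to
    the Mann-Whitney U implementation) and flagged in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:m].sum())
    ties = len(set(pooled)) < m + n
    if m + n <= exact_max_total and not ties:
        counts = _ranksum_counts(m + n, m)
        total = comb(m + n, m)
        mean_w = m * (m + n + 1) / 2.0
        dev = abs(w - mean_w)
        sums = np.arange(len(counts), dtype=float)
        p = float(counts[np.abs(sums - mean_w) >= dev - 1e-9].sum() / total)
        return TestResult(w, min(p, 1.0), "exact-convolution")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(w, float(res.pvalue), "normal-approximation" + (" (ties)" if ties else ""))


# ---------------------------------------------------------------------------
# cross-species overlap of aDMP calls

@dataclass(frozen=True)
class OverlapResult:
    n_only_a: int
    n_only_b: int
    n_both: int
    n_neither: int
    n_nonconserved_a: int
    n_nonconserved_b: int
    fraction_shared: float
    reference: str


def overlap_admps(
    admps_a: pd.MultiIndex,
    admps_b: pd.MultiIndex,
    mapping,
    reference: Literal["a", "b"] = "a",
) -> OverlapResult:
    """Overlap of aDMP calls restricted to conserved (mapped) sites.

    ``fraction_shared`` is n_both / (n_both + n_only_reference): of the
    reference side's conserved aDMPs, the fraction also called in the
    other species.  aDMPs outside the mapping are counted separately as
    non-conserved.
    """
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    set_a = set(map(tuple, admps_a))
    set_b = set(map(tuple, admps_b))
    pairs = list(
        zip(map(tuple, mapping.sites_a()), map(tuple, mapping.sites_b()))
    )
    mapped_a = {a for a, _ in pairs}
    mapped_b = {b for _, b in pairs}
    n_both = n_only_a = n_only_b = n_neither = 0
    for a, b in pairs:
        in_a, in_b = a in set_a, b in set_b
        if in_a and in_b:
            n_both += 1
        elif in_a:
            n_only_a += 1
        elif in_b:
            n_only_b += 1
        else:
            n_neither += 1
    n_ref = n_both + (n_only_a if reference == "a" else n_only_b)
    fraction = n_both / n_ref if n_ref else 0.0
    return OverlapResult(
        n_only_a=n_only_a,
        n_only_b=n_only_b,
        n_both=n_both,
        n_neither=n_neither,
        n_nonconserved_a=len(set_a - mapped_a),
        n_nonconserved_b=len(set_b - mapped_b),
        fraction_shared=fraction,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# species rate summaries and the lifespan correlation

def species_rate_summary(
    regions_by_species: Mapping[str, pd.DataFrame],
    species_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-species mean negative-log gradient over aDMP regions.

    ``species_meta`` is indexed by species name with a ``t_max_years``
    column.  Regions with exactly zero gradient are excluded (counted in
    the log); a species whose regions are all zero-gradient has no
    defined rate and raises.  Rows are sorted by T_max.
    """
    rows = []
    for species, regions in regions_by_species.items():
        if species not in species_meta.index:
            raise ValueError(f"species {species!r} missing from species_meta")
        grads = regions["gradient"].to_numpy(float)
        nonzero = grads != 0
        n_zero = int((~nonzero).sum())
        if n_zero:
            log.info("%s: excluded %d zero-gradient regions", species, n_zero)
        if not nonzero.any():
            raise ValueError(f"species {species!r} has no nonzero-gradient regions")
        rows.append(
            {
                "species": species,
                "t_max_years": float(species_meta.loc[species, "t_max_years"]),
                "mean_neg_log_gradient": float(np.mean(neg_log_gradient(grads[nonzero]))),
                "n_regions": int(nonzero.sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values("t_max_years").reset_index(drop=True)
    return out


def lifespan_correlation(summary: pd.DataFrame) -> TestResult:
    """Spearman correlation of mean -log10 gradient with T_max, exact p."""
    return spearman_exact(
        summary["t_max_years"].to_numpy(), summary["mean_neg_log_gradient"].to_numpy()
    )


# ---------------------------------------------------------------------------
# two-breed comparison

@dataclass(frozen=True)
class BreedComparison:
    pairs: pd.DataFrame  # region_id, gradient_1, gradient_2
    fraction_breed1_faster: float
    ranksum: TestResult


def breed_comparison(
    regions_breed1: pd.DataFrame,
    regions_breed2: pd.DataFrame,
    shared_region_ids: Sequence,
) -> BreedComparison:
    """Compare gradient magnitudes of regions called in both breeds.

    Emits the per-region gradient pairs (the y = x scatter data), the
    fraction of shared regions where breed 1's magnitude exceeds breed
    2's, and the rank-sum test on the two magnitude samples.  Works at
    either region or member-CpG granularity: pass whichever tables the
    ids index into.
    """
    if len(shared_region_ids) == 0:
        raise ValueError("no shared regions between the breeds")
    g1 = regions_breed1.loc[list(shared_region_ids), "gradient"].to_numpy(float)
    g2 = regions_breed2.loc[list(shared_region_ids), "gradient"].to_numpy(float)
    a1, a2 = np.abs(g1), np.abs(g2)
    pairs = pd.DataFrame(
        {"region_id": list(shared_region_ids), "gradient_1": g1, "gradient_2": g2}
    )
    return BreedComparison(
        pairs=pairs,
        fraction_breed1_faster=float((a1 > a2).mean()),
        ranksum=ranksum_exact(a1, a2),
    )


# ---------------------------------------------------------------------------
# paired-context (Tc1-style) gradient analysis

@dataclass(frozen=True)
class PairedGradientResult:
    pearson_r: float
    p_value: float
    fit_slope: float
    fit_intercept: float
    slope_through_origin: float
    ratios: pd.Series  # gradient_b / gradient_a, floor-filtered
    n_excluded: int


def paired_gradient_analysis(
    pairs: pd.DataFrame, ratio_floor: float = RATIO_FLOOR
) -> PairedGradientResult:
    """Relate the same sites' gradients in two cellular contexts.

    ``pairs`` needs ``gradient_a`` and ``gradient_b`` columns (context A
    e.g. the chromosome in its native species, context B the same
    chromosome in a faster-ageing host).  Reports the Pearson
    correlation of directionality with a two-sided p, the OLS slope of
    gradient_b on gradient_a (with intercept; through-origin slope also
    given) — the overall rate multiplier — and per-site ratios for sites
    with |gradient_a| >= ``ratio_floor``.
    """
    a = pairs["gradient_a"].to_numpy(float)
    b = pairs["gradient_b"].to_numpy(float)
    if len(a) < 3:
        raise ValueError("need at least 3 gradient pairs")
    if np.all(a == 0):
        raise ValueError("all context-A gradients are zero")
    if np.ptp(a) == 0:
        raise ValueError("context-A gradients are constant; slope undefined")
    res = stats.pearsonr(a, b)
    slope, intercept = np.polyfit(a, b, deg=1)
    usable = np.abs(a) >= ratio_floor
    ratios = pd.Series(b[usable] / a[usable], index=pairs.index[usable], name="ratio")
    return PairedGradientResult(
        pearson_r=float(res.statistic),
        p_value=float(res.pvalue),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        slope_through_origin=float((a @ b) / (a @ a)),
        ratios=ratios,
        n_excluded=int((~usable).sum()),
    )


def top_subset_ratio(
    pairs: pd.DataFrame, k: int, ratio_floor: float = RATIO_FLOOR
) -> tuple[float, int]:
    """Mean gradient ratio over the k pairs changing fastest in context B.

    Selects the k pairs with the largest |gradient_b|; pairs whose
    |gradient_a| falls below ``ratio_floor`` are excluded from the mean
    (their count is returned alongside).
    """
    if not 1 <= k <= len(pairs):
        raise ValueError("k must be between 1 and the number of pairs")
    order = np.argsort(-np.abs(pairs["gradient_b"].to_numpy(float)), kind="stable")
    top = pairs.iloc[order[:k]]
    a = top["gradient_a"].to_numpy(float)
    b = top["gradient_b"].to_numpy(float)
    usable = np.abs(a) >= ratio_floor
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("every selected pair falls below the ratio floor")
    return float(np.mean(b[usable] / a[usable])), n_excluded
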