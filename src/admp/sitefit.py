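"""Per-CpG age regression and aDMP calling.

The model at each CpG is ordinary least squares of the methylation
fraction on age in weeks:

    beta_i = intercept + gradient * age_weeks_i + eps_i

The fitted slope ("gradient", fraction/week) is the site's methylation
ageing rate; its two-sided t-test p-value (n - 2 df) and a Storey
positive-FDR q-value decide whether the site is an ageing-associated
differentially methylated position (aDMP).  Sites with zero variance in
methylation carry no age information and are flagged degenerate with
p = 1; a perfect noiseless linear trend drives the residual variance to
zero and its p-value is guarded at the smallest positive normal float.

Three selection regimes are supported, mirroring common practice across
assay platforms: a genome-scale q-value cutoff, a Benjamini-Hochberg
adjusted-p cutoff for targeted assays, and a raw-p cutoff for small-n
array studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from admp.ioformats import BetaMatrix, CountMatrix

log = logging.getLogger("admp.sitefit")

_P_FLOOR = float(np.finfo(np.float64).tiny)
# residual sum of squares below this fraction of the total SS counts as an
# exact fit (p underflow-guarded rather than divided by ~0)
_PERFECT_FIT_RTOL = 1e-16

FIT_COLUMNS = (
    "gradient",
    "intercept",
    "t_stat",
    "p_value",
    "q_value",
    "n_used",
    "degenerate",
)


@dataclass(frozen=True)
class FilterSpec:
    """Site/cell quality filters.

    ``min_coverage``: minimum read depth for a count cell to be usable.
    ``min_samples_at_coverage``: sites must reach ``min_coverage`` in at
    least this many samples to be retained (cohort-specific; e.g. 133 of
    153 in a large murine RRBS cohort).
    ``detection_p_max``: array probes with detection p above this are
    considered indistinguishable from background and blanked.
    """

    min_coverage: int = 50
    min_samples_at_coverage: int = 1
    detection_p_max: float = 0.01

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_samples_at_coverage < 1:
            raise ValueError("min_samples_at_coverage must be >= 1")
        if not 0 < self.detection_p_max < 1:
            raise ValueError("detection_p_max must be in (0, 1)")


def filter_coverage(counts: CountMatrix, spec: FilterSpec) -> CountMatrix:
    """Keep sites covered >= min_coverage deep in enough samples.

    Cells below ``min_coverage`` in retained sites are set missing
    (total 0) so shallow measurements never enter the regression.
    """
    if spec.min_samples_at_coverage > len(counts.samples):
        raise ValueError(
            "min_samples_at_coverage exceeds the number of samples"
        )
    tot = counts.total.to_numpy()
    ok = tot >= spec.min_coverage
    keep_sites = ok.sum(axis=1) >= spec.min_samples_at_coverage
    if not keep_sites.any():
        log.warning("coverage filter removed every site")
    meth = counts.methylated.to_numpy().copy()
    tot = tot.copy()
    meth[~ok] = 0
    tot[~ok] = 0
    return CountMatrix(
        pd.DataFrame(meth[keep_sites], index=counts.sites[keep_sites], columns=counts.samples),
        pd.DataFrame(tot[keep_sites], index=counts.sites[keep_sites], columns=counts.samples),
        counts.sample_meta,
    )


def filter_detection(beta: BetaMatrix, detection_p: pd.DataFrame, spec: FilterSpec) -> BetaMatrix:
    """Blank cells whose detection p exceeds the threshold (strict >).

    A cell at exactly ``detection_p_max`` is retained.  Sites losing all
    samples are dropped.
    """
    if detection_p.shape != beta.values.shape:
        raise ValueError(
            f"detection_p shape {detection_p.shape} does not match beta {beta.values.shape}"
        )
    vals = beta.values.to_numpy().copy()
    vals[detection_p.to_numpy() > spec.detection_p_max] = np.nan
    keep = ~np.all(np.isnan(vals), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("detection filter dropped %d all-missing sites", n_dropped)
    return BetaMatrix(
        pd.DataFrame(vals[keep], index=beta.sites[keep], columns=beta.samples),
        beta.sample_meta,
    )


def quantile_normalise_by_class(beta: BetaMatrix, probe_class: pd.Series) -> BetaMatrix:
    """Within each probe class, force all samples onto the mean quantile profile.

    Array probes fall into design classes (red channel, green channel,
    type II) with systematically different intensity distributions; each
    class is normalised separately.  For each sample the class values are
    ranked (average ranks for ties) and replaced by the class's mean
    empirical quantile function evaluated at those rank positions.
    Classes with fewer than two sites are passed through unchanged.
    """
    probe_class = probe_class.reindex(beta.sites)
    if probe_class.isna().any():
        missing = beta.sites[probe_class.isna()].tolist()
        raise ValueError(f"sites without a probe class label: {missing[:5]}")
    out = beta.values.to_numpy().copy()
    for cls, idx in probe_class.groupby(probe_class).groups.items():
        rows = beta.sites.get_indexer(idx)
        if len(rows) < 2:
            log.warning("probe class %r has < 2 sites; passed through", cls)
            continue
        out[rows] = _quantile_normalise_block(out[rows])
    return BetaMatrix(
        pd.DataFrame(out, index=beta.sites, columns=beta.samples), beta.sample_meta
    )


def _quantile_normalise_block(vals: np.ndarray) -> np.ndarray:
    """Normalise one class block (sites x samples), NaN-aware."""
    n_sites, n_samples = vals.shape
    # mean quantile profile: average the per-sample empirical quantile
    # functions at mid-rank plotting positions
    grids, sorteds = [], []
    for j in range(n_samples):
        col = vals[:, j]
        present = ~np.isnan(col)
        if present.sum() == 0:
            grids.append(None)
            sorteds.append(None)
            continue
        srt = np.sort(col[present])
        grids.append((np.arange(len(srt)) + 0.5) / len(srt))
        sorteds.append(srt)
    ref_grid = np.linspace(0, 1, 2 * n_sites + 1)[1::2]  # mid positions
    profiles = [
        np.interp(ref_grid, g, s) for g, s in zip(grids, sorteds) if g is not None
    ]
    if not profiles:
        return vals
    reference = np.mean(profiles, axis=0)
    out = np.full_like(vals, np.nan)
    for j in range(n_samples):
        col = vals[:, j]
        present = ~np.isnan(col)
        n = int(present.sum())
        if n == 0:
            continue
        ranks = stats.rankdata(col[present])  # average ranks on ties
        out[present, j] = np.interp((ranks - 0.5) / n, ref_grid, reference)
    return out


# ---------------------------------------------------------------------------
# the per-site linear model

def fit_site_linear(
    betas: Sequence[float], ages_weeks: Sequence[float]
) -> tuple[float, float, float, float, bool]:
    """OLS of one site's methylation on age.

    Returns (gradient, intercept, t_stat, p_value, degenerate).  NaN
    betas are dropped (complete-case); at least three complete cases and
    non-constant ages are required.
    """
    y = np.asarray(betas, dtype=float)
    x = np.asarray(ages_weeks, dtype=float)
    ok = ~np.isnan(y)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant: slope is unidentifiable")
    g, b0, t, p, d, _ = _fit_rows(y[None, :], np.broadcast_to(x, (1, len(x))))
    return float(g[0]), float(b0[0]), float(t[0]), float(p[0]), bool(d[0])


def _fit_rows(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised per-row OLS with NaN-masked y.

    ``y`` is sites x samples with NaN for missing, ``x`` the matching
    ages (broadcastable).  Rows are assumed pre-screened to have >= 3
    complete cases and non-constant x among them.
    """
    mask = ~np.isnan(y)
    n = mask.sum(axis=1).astype(float)
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y, 0.0)
    xbar = xm.sum(axis=1) / n
    ybar = ym.sum(axis=1) / n
    dx = np.where(mask, x - xbar[:, None], 0.0)
    dy = np.where(mask, y - ybar[:, None], 0.0)
    sxx = (dx * dx).sum(axis=1)
    sxy = (dx * dy).sum(axis=1)
    syy = (dy * dy).sum(axis=1)

    degenerate = syy == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        gradient = np.where(degenerate, 0.0, sxy / sxx)
        intercept = ybar - gradient * xbar
        sse = np.maximum(syy - gradient * sxy, 0.0)
        perfect = (~degenerate) & (sse <= _PERFECT_FIT_RTOL * syy)
        df = n - 2
        sigma2 = sse / df
        se = np.sqrt(sigma2 / sxx)
        t_stat = np.where(degenerate, 0.0, gradient / se)
    if perfect.any():
        t_stat[perfect] = np.sign(gradient[perfect]) * np.inf
    p = np.ones_like(gradient)
    normal = ~(degenerate | perfect)
    p[normal] = 2.0 * stats.t.sf(np.abs(t_stat[normal]), df[normal])
    p[perfect] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)
    return gradient, intercept, t_stat, p, degenerate, n.astype(int)


def call_admps(beta: BetaMatrix, min_samples: int = 3) -> pd.DataFrame:
    """Fit every eligible site; attach q-values over the non-degenerate set.

    Returns one row per eligible site, in input order, with columns
    gradient, intercept, t_stat, p_value, q_value, n_used, degenerate.
    Sites with fewer than ``min_samples`` complete cases, or constant
    ages among their complete cases, are skipped; the skipped sites and
    reasons are recorded in ``result.attrs["skipped"]``.  Degenerate
    (zero-variance) sites get p = q = 1 and are excluded from the null
    proportion estimate.
    """
    y = beta.values.to_numpy()
    x = np.broadcast_to(beta.ages_weeks, y.shape)
    mask = ~np.isnan(y)
    n_cc = mask.sum(axis=1)
    enough = n_cc >= max(min_samples, 3)
    xm = np.where(mask, x, np.nan)
    with np.errstate(invalid="ignore"):
        x_spread = np.nanmax(np.where(mask, x, -np.inf), axis=1) - np.nanmin(
            np.where(mask, x, np.inf), axis=1
        )
    identifiable = x_spread > 0
    eligible = enough & identifiable
    skipped = {}
    for i in np.flatnonzero(~eligible):
        reason = "too few complete cases" if not enough[i] else "constant ages"
        skipped[tuple(beta.sites[i])] = reason
    if not eligible.any():
        log.warning("no eligible sites for aDMP calling")
        empty = pd.DataFrame(columns=list(FIT_COLUMNS), index=beta.sites[:0])
        empty.attrs["skipped"] = skipped
        return empty

    g, b0, t, p, degen, n_used = _fit_rows(y[eligible], x[eligible])
    q = np.ones_like(p)
    nondegen = ~degen
    if nondegen.any():
        q[nondegen] = qvalues(p[nondegen])
    out = pd.DataFrame(
        {
            "gradient": g,
            "intercept": b0,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "n_used": n_used,
            "degenerate": degen,
        },
        index=beta.sites[eligible],
    )
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Storey positive-FDR q-values

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p: np.ndarray, small_m: int = 100, fixed_lambda: float = 0.5) -> float:
    """Storey estimate of the null proportion pi0.

    For m >= ``small_m`` p-values: evaluate pi0(lambda) over a lambda
    grid, fit a cubic smoother and read it off at the largest grid
    point.  For smaller m the grid estimates are too noisy to smooth, so
    the single fixed-lambda estimate is used.  Clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m >= small_m:
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in LAMBDA_GRID])
        coef = np.polynomial.polynomial.polyfit(LAMBDA_GRID, pi0_l, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(LAMBDA_GRID[-1], coef))
    else:
        pi0 = float((p > fixed_lambda).sum() / (m * (1 - fixed_lambda)))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p_values: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey positive-FDR q-values.

    q_(i) = pi0 * m * p_(i) / i, monotonised from the largest p
    downwards so q is non-decreasing in p; all outputs lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# selection regimes

SELECTION_RULES = ("q_max", "p_max", "adjusted_p_max")


def select_admps(fits: pd.DataFrame, rule: str, threshold: float) -> pd.DataFrame:
    """Select significant sites under one of three regimes.

    ``q_max`` thresholds the Storey q-value (genome-scale studies);
    ``adjusted_p_max`` thresholds Benjamini-Hochberg adjusted p-values
    (targeted assays); ``p_max`` thresholds the raw p (small-n array
    studies).  The rule, threshold and adjustment method used are
    recorded in ``result.attrs["selection"]``.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"unknown selection rule {rule!r}; choose from {SELECTION_RULES}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    meta = {"rule": rule, "threshold": threshold}
    if rule == "q_max":
        keep = fits["q_value"] <= threshold
    elif rule == "p_max":
        keep = fits["p_value"] <= threshold
    else:
        adj = np.ones(len(fits))
        nd = ~fits["degenerate"].to_numpy(bool)
        if nd.any():
            adj[nd] = stats.false_discovery_control(fits["p_value"].to_numpy()[nd], method="bh")
        keep = pd.Series(adj <= threshold, index=fits.index)
        meta["adjustment"] = "benjamini-hochberg"
    out = fits.loc[keep].copy()
    out.attrs["selection"] = meta
    return out
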