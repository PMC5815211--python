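"""Synthetic ageing-methylome generators with ground truth.

Each generator emulates the statistical structure of an ageing cohort:
a minority of CpG sites ("aDMPs") whose methylation fraction drifts
linearly with age in weeks, the remainder flat, observed through either
array-style beta values with additive noise or sequencing-style
binomial counts at a stated depth.  Slope magnitudes can be scaled by
species lifespan so that multi-species panels reproduce the
rate-vs-longevity structure of real comparative cohorts.

Every generator is deterministic given its seed, and every dataset is
accompanied by a truth table (per-site intercept, slope and aDMP flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from admp.ioformats import BetaMatrix, CountMatrix, MappingTable, site_index

TRUTH_COLUMNS = ("true_intercept", "true_slope", "is_admp")

# keep noiseless trajectories inside this band so clipping never engages
_BETA_LO, _BETA_HI = 0.02, 0.98

# default per-species sampling window as fractions of maximum lifespan
DEFAULT_AGE_FRACTIONS = (0.02, 0.60)

WEEKS_PER_YEAR = 52.1775


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``gradient_scale`` is the typical aDMP slope magnitude in methylation
    fraction per week; ``noise_sd`` the residual SD on the fraction scale
    (or on the logit scale for the logit-normal noise model);
    ``depth_mean`` the mean sequencing depth for count-mode data.
    """

    n_sites: int = 1000
    n_samples: int = 50
    age_range_weeks: tuple[float, float] = (10.0, 150.0)
    frac_admps: float = 0.1
    gradient_scale: float = 0.003
    noise_sd: float = 0.02
    depth_mean: float = 60.0
    seed: int = 0
    noise_model: str = "gaussian"  # or "logit"
    site_spacing: int = 1000
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_samples < 1:
            raise ValueError("n_sites and n_samples must be positive")
        lo, hi = self.age_range_weeks
        if not (0 <= lo < hi):
            raise ValueError("age_range_weeks must satisfy 0 <= min < max")
        if not 0 <= self.frac_admps <= 1:
            raise ValueError("frac_admps must be in [0, 1]")
        if self.gradient_scale <= 0:
            raise ValueError("gradient_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "logit"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-site intercepts/slopes; aDMP intercepts stay feasible in [0,1]."""
    n = config.n_sites
    n_admp = int(round(config.frac_admps * n))
    is_admp = np.zeros(n, dtype=bool)
    is_admp[rng.choice(n, size=n_admp, replace=False)] = True

    slopes = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_admp)
    magnitudes = config.gradient_scale * rng.uniform(0.7, 1.3, size=n_admp)
    slopes[is_admp] = signs * magnitudes

    lo_age, hi_age = config.age_range_weeks
    intercepts = rng.uniform(_BETA_LO, _BETA_HI, size=n)
    # for drifting sites, restrict the intercept so the noiseless line
    # stays inside [_BETA_LO, _BETA_HI] over the whole age range
    s = slopes[is_admp]
    ends = np.stack([s * lo_age, s * hi_age])
    feas_lo = _BETA_LO - ends.min(axis=0)
    feas_hi = _BETA_HI - ends.max(axis=0)
    if (feas_hi <= feas_lo).any():
        raise ValueError(
            "gradient_scale too large for the age range: no intercept keeps "
            "the methylation trajectory inside [0, 1]"
        )
    intercepts[is_admp] = feas_lo + (feas_hi - feas_lo) * rng.uniform(size=n_admp)

    positions = np.arange(n, dtype=np.int64) * config.site_spacing + config.site_spacing
    index = site_index([config.chrom] * n, positions)
    return pd.DataFrame(
        {"true_intercept": intercepts, "true_slope": slopes, "is_admp": is_admp},
        index=index,
    )


def expected_beta(truth: pd.DataFrame, ages_weeks: np.ndarray) -> np.ndarray:
    """Noiseless site x sample methylation surface implied by a truth table."""
    mu = (
        truth["true_intercept"].to_numpy()[:, None]
        + truth["true_slope"].to_numpy()[:, None] * np.asarray(ages_weeks)[None, :]
    )
    return np.clip(mu, 0.0, 1.0)


def synthesize_betas(
    truth: pd.DataFrame,
    ages_weeks: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    noise_model: str = "gaussian",
) -> np.ndarray:
    """Observe the truth surface under the chosen noise model.

    Gaussian: beta = clip(mu + N(0, sd), 0, 1) -- simple but biased near
    the boundaries.  Logit-normal: noise added on the logit scale, which
    respects (0, 1) without clipping.
    """
    mu = expected_beta(truth, ages_weeks)
    if noise_sd == 0:
        return mu
    if rng is None:
        rng = np.random.default_rng(0)
    eps = rng.normal(0.0, noise_sd, size=mu.shape)
    if noise_model == "gaussian":
        return np.clip(mu + eps, 0.0, 1.0)
    if noise_model == "logit":
        mu_safe = np.clip(mu, 1e-6, 1 - 1e-6)
        return expit(logit(mu_safe) + eps)
    raise ValueError(f"unknown noise_model {noise_model!r}")


def _sample_meta(config: SimConfig, ages: np.ndarray, species: str = "synthetic", group: str = "all") -> pd.DataFrame:
    ids = [f"s{i:03d}" for i in range(config.n_samples)]
    return pd.DataFrame(
        {"age_weeks": ages, "species": species, "group": group},
        index=pd.Index(ids, name="sample_id"),
    )


def generate_beta_dataset(config: SimConfig) -> tuple[BetaMatrix, pd.DataFrame]:
    """Array-style cohort: beta values observed with additive noise."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    ages = rng.uniform(*config.age_range_weeks, size=config.n_samples)
    betas = synthesize_betas(truth, ages, config.noise_sd, rng, config.noise_model)
    meta = _sample_meta(config, ages)
    values = pd.DataFrame(betas, index=truth.index, columns=meta.index)
    return BetaMatrix(values, meta), truth


def synthesize_counts(
    truth: pd.DataFrame,
    ages_weeks: np.ndarray,
    depth_mean: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson total depth, binomial methylated counts at the true beta."""
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    mu = expected_beta(truth, ages_weeks)
    total = rng.poisson(depth_mean, size=mu.shape)
    meth = rng.binomial(total, mu)
    return meth, total


def generate_count_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Sequencing-style cohort: Poisson depth, binomial methylated counts.

    Zero-depth cells are missing (total 0).  The binomial draw uses the
    noiseless true beta; sequencing noise itself supplies the residual
    scatter, so ``noise_sd`` is ignored in count mode.
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    ages = rng.uniform(*config.age_range_weeks, size=config.n_samples)
    meth, total = synthesize_counts(truth, ages, config.depth_mean, rng)
    meta = _sample_meta(config, ages)
    return (
        CountMatrix(
            pd.DataFrame(meth, index=truth.index, columns=meta.index),
            pd.DataFrame(total, index=truth.index, columns=meta.index),
            meta,
        ),
        truth,
    )


# ---------------------------------------------------------------------------
# multi-species panels

def default_rate_rule(t_max_years: float, c: float = 0.02) -> float:
    """Slope scale proportional to 1 / T_max.

    With the default age window spanning a fixed fraction of lifespan,
    this gives every species the same total methylation excursion, so
    short-lived species drift proportionally faster per week.
    """
    return c / t_max_years


def generate_species_panel(
    species: Sequence[tuple[str, float]],
    rate_rule: Callable[[float], float] = default_rate_rule,
    per_species: Mapping[str, SimConfig] | None = None,
    base_config: SimConfig | None = None,
    age_fractions: tuple[float, float] = DEFAULT_AGE_FRACTIONS,
) -> dict[str, tuple[BetaMatrix, pd.DataFrame]]:
    """One cohort per species with lifespan-scaled aDMP slopes.

    ``species`` is a list of (name, T_max in years).  Each species' age
    range spans ``age_fractions`` of its lifespan (in weeks) and its
    gradient scale is ``rate_rule(t_max)``; both can be overridden per
    species via ``per_species``.
    """
    names = [name for name, _ in species]
    if len(species) < 2:
        raise ValueError("a panel needs at least two species")
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in panel")
    tmaxs = [t for _, t in species]
    if len(set(tmaxs)) != len(tmaxs):
        raise ValueError("species T_max values must be distinct")
    base = base_config or SimConfig()
    panel: dict[str, tuple[BetaMatrix, pd.DataFrame]] = {}
    for k, (name, t_max) in enumerate(species):
        if per_species and name in per_species:
            cfg = per_species[name]
        else:
            lo = age_fractions[0] * t_max * WEEKS_PER_YEAR
            hi = age_fractions[1] * t_max * WEEKS_PER_YEAR
            cfg = replace(
                base,
                age_range_weeks=(lo, hi),
                gradient_scale=rate_rule(t_max),
                seed=base.seed + k,
            )
        beta, truth = generate_beta_dataset(cfg)
        beta.sample_meta["species"] = name
        panel[name] = (beta, truth)
    return panel


# ---------------------------------------------------------------------------
# cross-species correspondence tables

def generate_mapping(
    sites_a: pd.MultiIndex,
    sites_b: pd.MultiIndex,
    conserved_fraction: float,
    seed: int = 0,
) -> MappingTable:
    """Random 1:1 correspondence over a conserved subset of sites.

    Each candidate pair is retained independently with probability
    ``conserved_fraction`` (Bernoulli sampling, so the mapped count is
    binomial rather than fixed-size).  Match fractions are drawn uniform
    on [0.9, 1.0], mirroring a liftOver run at minMatch 0.9.
    """
    if not 0 <= conserved_fraction <= 1:
        raise ValueError("conserved_fraction must be in [0, 1]")
    if len(sites_a) == 0 or len(sites_b) == 0:
        raise ValueError("site sets must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(sites_a), len(sites_b))
    order_a = rng.permutation(len(sites_a))[:n]
    order_b = rng.permutation(len(sites_b))[:n]
    if conserved_fraction == 1.0:
        keep = np.ones(n, dtype=bool)
    else:
        keep = rng.uniform(size=n) < conserved_fraction
    a = sites_a[order_a[keep]]
    b = sites_b[order_b[keep]]
    table = pd.DataFrame(
        {
            "chrom_a": a.get_level_values("chrom"),
            "pos_a": a.get_level_values("pos"),
            "chrom_b": b.get_level_values("chrom"),
            "pos_b": b.get_level_values("pos"),
            "match_fraction": rng.uniform(0.9, 1.0, size=int(keep.sum())),
        }
    )
    table = table.sort_values(["chrom_a", "pos_a"]).reset_index(drop=True)
    return MappingTable(table)


# ---------------------------------------------------------------------------
# paired contexts (human chr21 vs the same chromosome in a Tc1-like host)

def generate_paired_contexts(
    base_truth: pd.DataFrame,
    scale_factor: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_samples: tuple[int, int] = (30, 30),
    age_ranges_weeks: tuple[tuple[float, float], tuple[float, float]] = (
        (988.0, 5252.0),  # human blood cohort window
        (8.0, 52.0),      # transchromosomic mouse window
    ),
) -> tuple[BetaMatrix, BetaMatrix, pd.DataFrame]:
    """Two cohorts sharing sites and slope signs, context B sped up.

    Context B's slopes are ``scale_factor`` times context A's in
    magnitude with identical signs, emulating the same chromosome ageing
    in a short-lived host.  B's age window is typically much shorter.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    rng = np.random.default_rng(seed)
    truth_a = base_truth.copy()
    truth_b = base_truth.copy()
    truth_b["true_slope"] = base_truth["true_slope"] * scale_factor
    # re-draw each context's intercepts inside the band that keeps its own
    # noiseless trajectory off the [0, 1] boundary, so clipping never biases
    # the planted slopes
    for truth, (lo, hi) in zip((truth_a, truth_b), age_ranges_weeks):
        s = truth["true_slope"].to_numpy()
        ends = np.stack([s * lo, s * hi])
        feas_lo = _BETA_LO - ends.min(axis=0)
        feas_hi = _BETA_HI - ends.max(axis=0)
        if (feas_hi <= feas_lo).any():
            raise ValueError(
                "slopes leave no feasible intercept for the context age window"
            )
        truth["true_intercept"] = feas_lo + (feas_hi - feas_lo) * rng.uniform(size=len(s))

    matrices = []
    for truth, n, (lo, hi), label in (
        (truth_a, n_samples[0], age_ranges_weeks[0], "a"),
        (truth_b, n_samples[1], age_ranges_weeks[1], "b"),
    ):
        ages = rng.uniform(lo, hi, size=n)
        betas = synthesize_betas(truth, ages, noise_sd, rng)
        ids = [f"{label}{i:03d}" for i in range(n)]
        meta = pd.DataFrame(
            {"age_weeks": ages, "species": f"context_{label}", "group": label},
            index=pd.Index(ids, name="sample_id"),
        )
        matrices.append(BetaMatrix(pd.DataFrame(betas, index=truth.index, columns=ids), meta))

    truth = truth_a.rename(columns={"true_slope": "true_slope_a"})
    truth["true_slope_b"] = truth_b["true_slope"]
    truth["intercept_b"] = truth_b["true_intercept"]
    return matrices[0], matrices[1], truth
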