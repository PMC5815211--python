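"""Comparative layer: exact tests, overlap bookkeeping, rate summaries, ratios."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admp import crossspecies as cs
from admp import simdata, sitefit
from admp.ioformats import site_index
from admp.simdata import SimConfig


class TestNegLogGradient:
    def test_powers_of_ten_and_sign_invariance(self):
        assert cs.neg_log_gradient(0.001) == pytest.approx(3.0)
        assert cs.neg_log_gradient(-0.001) == pytest.approx(3.0)
        assert cs.neg_log_gradient(0.0048) == pytest.approx(2.3188, abs=1e-4)

    def test_zero_gradient_rejected(self):
        with pytest.raises(ValueError):
            cs.neg_log_gradient(0.0)


def brute_force_spearman_p(x, y):
    """Oracle: per-permutation rho via np.corrcoef on ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    perms = list(permutations(ry))
    for perm in perms:
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / len(perms)


def brute_force_ranksum_p(x, y):
    """Oracle: enumerate all C(m+n, m) labelings of the pooled ranks."""
    m, total = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:m].sum()
    all_ranks = np.arange(1, total + 1)
    mean_w = m * (total + 1) / 2
    hits = trials = 0
    for combo in combinations(all_ranks, m):
        trials += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            hits += 1
    return w_obs, hits / trials


class TestSpearmanExact:
    def test_monotone_six_species_exact_p(self):
        res = cs.spearman_exact([4, 24, 31, 40, 95, 122], [2.1, 2.4, 2.5, 2.6, 3.0, 3.1])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 720)
        assert res.method == "exact-permutation"

    def test_antitone_symmetry(self):
        res = cs.spearman_exact([1, 2, 3, 4, 5, 6], [9, 8, 7, 6, 5, 4])
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(2 / 720)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 7))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            res = cs.spearman_exact(x, y)
            rho_o, p_o = brute_force_spearman_p(x, y)
            assert res.statistic == pytest.approx(rho_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_ties_fall_back_to_approximation(self):
        res = cs.spearman_exact([1, 1, 2, 3, 4], [5, 6, 7, 8, 9])
        assert "ties" in res.method

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cs.spearman_exact([1, 2, 3], [1, 2])


class TestRanksumExact:
    def test_balanced_samples_p_one(self):
        # rank sum exactly at its null mean: every arrangement is at least
        # as extreme, so p = 1
        res = cs.ranksum_exact([1.0, 4.0, 5.0], [2.0, 3.0, 6.0])
        assert res.p_value == pytest.approx(1.0)

    def test_identical_samples_near_one(self):
        res = cs.ranksum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.95  # tie-corrected approximation

    def test_complete_separation_six_vs_six(self):
        res = cs.ranksum_exact(np.arange(6.0), np.arange(10.0, 16.0))
        assert res.p_value == pytest.approx(2 / 924)
        assert res.method == "exact-convolution"

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 11 - m))
            pooled = rng.permutation(m + n).astype(float)  # distinct values
            x, y = pooled[:m], pooled[m:]
            res = cs.ranksum_exact(x, y)
            w_o, p_o = brute_force_ranksum_p(x, y)
            assert res.statistic == pytest.approx(w_o)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_ties_use_flagged_approximation(self):
        res = cs.ranksum_exact([1.0, 1.0, 2.0], [1.0, 3.0, 4.0])
        assert "ties" in res.method

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.ranksum_exact([], [1.0])


def cs_identity_mapping(sites):
    from admp.ioformats import MappingTable

    return MappingTable(
        pd.DataFrame(
            {
                "chrom_a": sites.get_level_values("chrom"),
                "pos_a": sites.get_level_values("pos"),
                "chrom_b": sites.get_level_values("chrom"),
                "pos_b": sites.get_level_values("pos"),
                "match_fraction": 0.95,
            }
        )
    )


class TestOverlap:
    def _sites(self, n, chrom):
        return site_index([chrom] * n, np.arange(n) * 10)

    def test_identical_sets_under_identity_mapping(self):
        sites = self._sites(20, "chr1")
        mapping = simdata.generate_mapping(sites, sites, 1.0, seed=0)
        res = cs.overlap_admps(sites, mapping.sites_b(), mapping, reference="a")
        # every mapped a-side aDMP maps to a b-side aDMP
        assert res.fraction_shared == 1.0

    def test_disjoint_sets(self):
        sites = self._sites(20, "chr1")
        identity = cs_identity_mapping(sites)
        res = cs.overlap_admps(sites[:10], sites[10:], identity, reference="a")
        assert res.n_both == 0
        assert res.fraction_shared == 0.0

    def test_planted_seventy_percent_shared(self, rng):
        n = 1000
        a_sites = self._sites(n, "chrA")
        b_sites = self._sites(n, "chrB")
        mapping = simdata.generate_mapping(a_sites, b_sites, 1.0, seed=5)
        admps_a = mapping.sites_a()
        shared = rng.uniform(size=n) < 0.70
        admps_b = mapping.sites_b()[shared]
        res = cs.overlap_admps(admps_a, admps_b, mapping, reference="a")
        half_width = 2.576 * np.sqrt(0.7 * 0.3 / n)
        assert abs(res.fraction_shared - 0.70) <= half_width

    def test_bookkeeping_adds_up(self, rng):
        n = 200
        a_sites = self._sites(n, "chrA")
        b_sites = self._sites(n, "chrB")
        mapping = simdata.generate_mapping(a_sites, b_sites, 0.6, seed=9)
        admps_a = a_sites[rng.uniform(size=n) < 0.4]
        admps_b = b_sites[rng.uniform(size=n) < 0.4]
        res = cs.overlap_admps(admps_a, admps_b, mapping, reference="a")
        conserved_a = set(map(tuple, mapping.sites_a())) & set(map(tuple, admps_a))
        assert res.n_only_a + res.n_both == len(conserved_a)
        assert res.n_nonconserved_a == len(admps_a) - len(conserved_a)

    def test_bad_reference_rejected(self):
        sites = self._sites(5, "chr1")
        mapping = simdata.generate_mapping(sites, sites, 1.0, seed=0)
        with pytest.raises(ValueError):
            cs.overlap_admps(sites, sites, mapping, reference="c")


class TestSpeciesRateSummary:
    def _meta(self, names, tmaxs):
        return pd.DataFrame({"t_max_years": tmaxs}, index=pd.Index(names, name="species"))

    def _regions(self, gradients):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(gradients)) * 1000,
                "end": np.arange(len(gradients)) * 1000 + 200,
                "n_admps": 1,
                "gradient": gradients,
                "min_p": 1e-6,
            }
        )

    def test_single_region_mean_is_its_value(self):
        out = cs.species_rate_summary(
            {"mouse": self._regions([0.001])}, self._meta(["mouse"], [4.0])
        )
        assert out["mean_neg_log_gradient"].iloc[0] == pytest.approx(3.0)
        assert out["n_regions"].iloc[0] == 1

    def test_arithmetic_example(self):
        out = cs.species_rate_summary(
            {"dog": self._regions([0.001, 0.0001])}, self._meta(["dog"], [24.0])
        )
        assert out["mean_neg_log_gradient"].iloc[0] == pytest.approx(3.5)

    def test_all_zero_gradients_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            cs.species_rate_summary(
                {"x": self._regions([0.0])}, self._meta(["x"], [1.0])
            )

    def test_zero_gradient_regions_excluded_not_dropped_silently(self, caplog):
        with caplog.at_level("INFO", logger="admp.crossspecies"):
            out = cs.species_rate_summary(
                {"x": self._regions([0.001, 0.0])}, self._meta(["x"], [1.0])
            )
        assert out["n_regions"].iloc[0] == 1
        assert "excluded 1 zero-gradient" in caplog.text


SPECIES = [
    ("mouse", 4.0),
    ("dog", 24.0),
    ("nmr", 31.0),
    ("macaque", 40.0),
    ("whale", 95.0),
    ("human", 122.0),
]


def run_panel_pipeline(seed=0, noise_sd=0.0):
    """Full pipeline: simulate panel -> call -> select -> regions -> summary."""
    from admp import regions as reg

    base = SimConfig(
        n_sites=120, n_samples=12, frac_admps=0.25, noise_sd=noise_sd, seed=seed
    )
    panel = simdata.generate_species_panel(SPECIES, base_config=base)
    regions_by_species = {}
    for name, (beta, _) in panel.items():
        fits = sitefit.call_admps(beta)
        sel = sitefit.select_admps(fits, "q_max", 0.01)
        regions_by_species[name] = reg.make_regions(sel)
    meta = pd.DataFrame(
        {"t_max_years": dict(SPECIES)}
    ).rename_axis("species")
    return cs.species_rate_summary(regions_by_species, meta)


class TestLifespanCorrelation:
    def test_monotone_panel_gives_exact_rho_one(self):
        summary = run_panel_pipeline(seed=0)
        assert (summary["mean_neg_log_gradient"].diff().dropna() > 0).all()
        res = cs.lifespan_correlation(summary)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 720)


class TestBreedComparison:
    def _regions(self, gradients):
        return pd.DataFrame(
            {"gradient": gradients},
            index=pd.Index([f"r{i}" for i in range(len(gradients))], name="region_id"),
        )

    def test_half_rate_breed_always_slower(self):
        g1 = np.array([0.004, -0.003, 0.002, 0.005, -0.001, 0.0025])
        b = cs.breed_comparison(
            self._regions(g1), self._regions(0.5 * g1), [f"r{i}" for i in range(6)]
        )
        assert b.fraction_breed1_faster == 1.0

    def test_identical_gradients_p_one(self):
        g = np.array([0.004, -0.003, 0.002])
        b = cs.breed_comparison(self._regions(g), self._regions(g), ["r0", "r1", "r2"])
        assert b.fraction_breed1_faster == 0.0
        assert b.ranksum.p_value == pytest.approx(1.0)

    def test_simulated_two_breed_panel(self):
        # short-lived breed ages 1.4x faster; at low noise it wins every region
        rng = np.random.default_rng(3)
        slow = rng.uniform(0.002, 0.004, 6) * rng.choice([-1, 1], 6)
        fast = 1.4 * slow * (1 + rng.normal(0, 0.02, 6))
        b = cs.breed_comparison(
            self._regions(fast), self._regions(slow), [f"r{i}" for i in range(6)]
        )
        assert b.fraction_breed1_faster == 1.0
        assert b.ranksum.p_value < 0.05

    def test_no_shared_regions_rejected(self):
        with pytest.raises(ValueError):
            cs.breed_comparison(self._regions([0.1]), self._regions([0.1]), [])


class TestPairedGradients:
    def _pairs(self, a, b):
        return pd.DataFrame(
            {"gradient_a": a, "gradient_b": b},
            index=site_index(["chr21"] * len(a), np.arange(len(a)) * 100),
        )

    def test_exact_21x_scaling(self, rng):
        a = rng.choice([-1, 1], 15) * rng.uniform(0.5, 1.5, 15) * 1e-4
        res = cs.paired_gradient_analysis(self._pairs(a, 21.0 * a))
        assert res.fit_slope == pytest.approx(21.0, rel=1e-12)
        assert res.slope_through_origin == pytest.approx(21.0, rel=1e-12)
        assert res.pearson_r == pytest.approx(1.0)
        np.testing.assert_allclose(res.ratios, 21.0)

    def test_identity_and_antisymmetry(self, rng):
        a = rng.uniform(1e-4, 5e-4, 10) * rng.choice([-1, 1], 10)
        same = cs.paired_gradient_analysis(self._pairs(a, a.copy()))
        assert same.fit_slope == pytest.approx(1.0)
        np.testing.assert_allclose(same.ratios, 1.0)
        flipped = cs.paired_gradient_analysis(self._pairs(a, -a))
        assert flipped.pearson_r == pytest.approx(-1.0)

    def test_ratio_floor_exclusions_counted(self):
        a = np.array([1e-4, 2e-4, 1e-9])
        res = cs.paired_gradient_analysis(self._pairs(a, 2 * a))
        assert res.n_excluded == 1
        assert len(res.ratios) == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.paired_gradient_analysis(self._pairs(np.zeros(5), np.ones(5)))
        with pytest.raises(ValueError):
            cs.paired_gradient_analysis(self._pairs([1e-4, 1e-4], [1e-4, 1e-4]))


class TestTopSubsetRatio:
    def _pairs(self, a, b):
        return pd.DataFrame(
            {"gradient_a": a, "gradient_b": b},
            index=site_index(["chr21"] * len(a), np.arange(len(a)) * 100),
        )

    def test_uniform_ratio_recovered_at_k_n(self):
        a = np.linspace(1e-4, 5e-4, 8)
        mean, excl = cs.top_subset_ratio(self._pairs(a, 7.0 * a), k=8)
        assert mean == pytest.approx(7.0)
        assert excl == 0

    def test_k_one_selects_largest_b(self):
        a = np.array([1e-4, 2e-4, 3e-4])
        b = np.array([5e-4, 1e-3, 2e-4])
        mean, _ = cs.top_subset_ratio(self._pairs(a, b), k=1)
        assert mean == pytest.approx(1e-3 / 2e-4)

    def test_two_population_ratios_recovered(self, rng):
        # bulk of sites at 21x, the fastest-changing subset at 35x
        a = rng.uniform(1.0, 1.5, 15) * 1e-4
        b = 21.0 * a
        b[:4] = 35.0 * rng.uniform(2.0, 2.5, 4) * 1e-4  # largest |gradient_b|
        a[:4] = b[:4] / 35.0
        mean, _ = cs.top_subset_ratio(self._pairs(a, b), k=4)
        assert mean == pytest.approx(35.0, rel=1e-9)

    def test_k_out_of_range_rejected(self):
        a = np.linspace(1e-4, 5e-4, 5)
        with pytest.raises(ValueError):
            cs.top_subset_ratio(self._pairs(a, a), k=0)
        with pytest.raises(ValueError):
            cs.top_subset_ratio(self._pairs(a, a), k=6)
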