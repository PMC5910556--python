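"""Population-genetic statistics against hand-evaluated and enumeration
oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhcdemekit.popgen import (
    average_relatedness,
    dloop_sharing,
    fisher_exact_2x2,
    fst_weir_cockerham,
    heterozygosity_stats,
    hwe_exact_test,
    pooled_frequencies,
    rarefaction_curve,
    rarefaction_expected,
    relatedness_qg,
    sample_size_correlation,
)


class TestHeterozygosity:
    def test_monomorphic_deme(self):
        h_obs, h_exp, n_eff = heterozygosity_stats([("A", "A")] * 8)
        assert (h_obs, h_exp, n_eff) == (0.0, 0.0, 1.0)

    def test_two_alleles_at_half(self):
        _, _, n_eff = heterozygosity_stats([("A", "B"), ("A", "B")])
        assert n_eff == pytest.approx(2.0)

    def test_hand_evaluated_unbiased_form(self):
        h_obs, h_exp, _ = heterozygosity_stats([("A", "B"), ("A", "B")])
        assert h_obs == 1.0
        assert h_exp == pytest.approx(4 / 3 * 0.5)   # 0.6667

    def test_unbiasedness_under_sampling(self, rng):
        """Mean h_exp over repeated samples converges to 1 - sum p^2."""
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - np.sum(p ** 2)
        vals = []
        for _ in range(400):
            draws = rng.choice(3, size=(12, 2), p=p)
            _, he, _ = heterozygosity_stats([tuple(g) for g in draws])
            vals.append(he)
        assert abs(np.mean(vals) - target) < 3 * np.std(vals) / 20

    def test_empty_deme_rejected(self):
        with pytest.raises(ValueError):
            heterozygosity_stats([])


class TestHWE:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test({("A", "A"): 5}) == 1.0

    def test_two_homozygotes_enumeration(self):
        """AA=1, aa=1: configurations h in {0,2} with conditional
        probabilities 1/3 and 2/3 -> p = 1/3."""
        assert hwe_exact_test({("A", "A"): 1, ("a", "a"): 1}) == \
            pytest.approx(1 / 3)

    def test_mc_agrees_with_enumeration(self):
        counts = {("A", "A"): 4, ("A", "B"): 1, ("B", "B"): 6,
                  ("A", "C"): 2, ("C", "C"): 1}
        p_enum = hwe_exact_test(counts)
        p_mc = hwe_exact_test(counts, enumeration_limit=1, mc_reps=100_000,
                              seed=5)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_type_one_error_near_nominal(self, rng):
        """Rejection rate at alpha=0.05 under HWE (small-scale check; the
        full 1000-replicate calibration runs in the acceptance suite)."""
        rej = 0
        nsim = 300
        for s in range(nsim):
            p = rng.dirichlet(np.ones(5))
            g = rng.choice(5, size=(50, 2), p=p)
            counts = {}
            for a, b in g:
                key = tuple(sorted((int(a), int(b))))
                counts[key] = counts.get(key, 0) + 1
            rej += hwe_exact_test(counts, mc_reps=1000, seed=s) < 0.05
        assert 0.02 <= rej / nsim <= 0.08


class TestFst:
    def test_identical_demes_near_zero(self):
        g = [("A", "B")] * 25 + [("A", "A")] * 15 + [("B", "B")] * 10
        theta = fst_weir_cockerham({"d1": {"L": g}, "d2": {"L": g}})
        assert abs(theta.loc["d1", "d2"]) < 0.03

    def test_fixed_demes_theta_one(self):
        theta = fst_weir_cockerham({"d1": {"L": [("A", "A")] * 20},
                                    "d2": {"L": [("B", "B")] * 20}})
        assert theta.loc["d1", "d2"] == pytest.approx(1.0)

    def test_three_deme_fixture_against_component_transcription(self):
        """Direct independent evaluation of the estimator's variance
        components on a printed fixture."""
        demes = {
            "x": {"L": [("A", "A"), ("A", "B"), ("B", "B"), ("A", "A")]},
            "y": {"L": [("A", "B"), ("A", "B"), ("A", "A"), ("A", "A")]},
            "z": {"L": [("B", "B"), ("B", "B"), ("A", "B"), ("B", "B")]},
        }
        theta = fst_weir_cockerham(demes)

        def oracle(g1, g2):
            r = 2
            n = np.array([len(g1), len(g2)], dtype=float)
            nbar = n.mean()
            nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)
            num = den = 0.0
            for al in {"A", "B"}:
                p = np.array([
                    sum((x == al) + (y == al) for x, y in g1) / (2 * n[0]),
                    sum((x == al) + (y == al) for x, y in g2) / (2 * n[1])])
                h = np.array([
                    sum((x == al) != (y == al) for x, y in g1) / n[0],
                    sum((x == al) != (y == al) for x, y in g2) / n[1]])
                pbar = np.sum(n * p) / (r * nbar)
                s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
                hbar = np.sum(n * h) / (r * nbar)
                a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
                                   / (nbar - 1))
                b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                           - hbar * (2 * nbar - 1) / (4 * nbar))
                c = hbar / 2
                num += a
                den += a + b + c
            return num / den

        for d1, d2 in (("x", "y"), ("x", "z"), ("y", "z")):
            assert theta.loc[d1, d2] == pytest.approx(
                oracle(demes[d1]["L"], demes[d2]["L"]))

    def test_island_model_theta_decreases_with_migration(self, rng):
        """More migration -> lower differentiation (parameter recovery)."""
        def island(m):
            base = ["A", "B", "C", "D"]
            freqs = {"d1": np.array([0.7, 0.1, 0.1, 0.1]),
                     "d2": np.array([0.1, 0.7, 0.1, 0.1])}
            mixed = {d: (1 - m) * f + m * np.array([0.25] * 4)
                     for d, f in freqs.items()}
            out = {}
            for d, f in mixed.items():
                f = f / f.sum()
                draws = rng.choice(4, size=(60, 2), p=f)
                out[d] = {"L": [(base[a], base[b]) for a, b in draws]}
            return fst_weir_cockerham(out).loc["d1", "d2"]

        thetas = [np.mean([island(m) for _ in range(5)])
                  for m in (0.0, 0.5, 1.0)]
        assert thetas[0] > thetas[1] > thetas[2]


class TestRelatedness:
    def test_identical_heterozygotes_r_one(self):
        # frequencies must leave the pair informative (a two-allele locus
        # where the het carries both alleles has zero QG denominator)
        f = {"L1": {"A": 0.3, "B": 0.2, "C": 0.5},
             "L2": {"X": 0.4, "Y": 0.4, "Z": 0.2}}
        g = {"L1": ("A", "B"), "L2": ("X", "Y")}
        assert relatedness_qg(g, g, f) == pytest.approx(1.0)

    def test_unrelated_pairs_mean_zero(self, rng):
        f = {f"L{k}": {} for k in range(8)}
        freqs = {}
        for k in range(8):
            p = rng.dirichlet(np.ones(6))
            freqs[f"L{k}"] = {f"a{i}": p[i] for i in range(6)}
        vals = []
        for _ in range(1000):
            g1, g2 = {}, {}
            for k in range(8):
                p = np.array(list(freqs[f"L{k}"].values()))
                a = rng.choice(6, size=2, p=p)
                b = rng.choice(6, size=2, p=p)
                g1[f"L{k}"] = (f"a{a[0]}", f"a{a[1]}")
                g2[f"L{k}"] = (f"a{b[0]}", f"a{b[1]}")
            vals.append(relatedness_qg(g1, g2, freqs))
        mc_err = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * mc_err + 0.01

    def test_parent_offspring_half(self):
        """Simulator pedigree: parent-offspring QG relatedness ~ 0.5."""
        from mhcdemekit.synthdata import SimConfig, simulate_metapopulation
        vals = []
        for seed in range(6):
            # a large multi-deme pool keeps the frequency estimates nearly
            # free of the focal family's own alleles
            cfg = SimConfig(n_regions=1, demes_per_region=10,
                            individuals_per_deme=(8, 12),
                            n_msat_founder_alleles=14,
                            loci={"H2-Aa": 208}, migration_rate=0.0,
                            seed=400 + seed)
            truth = simulate_metapopulation(cfg)
            genos = {i.id: {f"m{m}": g for m, g in i.microsats.items()}
                     for i in truth.individuals}
            freqs = pooled_frequencies(genos)
            by_id = {i.id: i for i in truth.individuals}
            for ind in truth.individuals:
                if ind.mother:
                    vals.append(relatedness_qg(genos[ind.id],
                                               genos[ind.mother], freqs))
        assert abs(np.mean(vals) - 0.5) < 0.05


class TestRarefaction:
    def test_full_sample_gives_distinct_count(self):
        assert rarefaction_expected([4, 3, 2, 1], 10) == pytest.approx(4.0)

    def test_single_copy_gives_one(self):
        assert rarefaction_expected([4, 3, 2, 1], 1) == pytest.approx(1.0)

    def test_exhaustive_enumeration_small_case(self):
        # counts (2,1), n=2: subsets {ab}{ab'}{bb'} -> distinct 2,2,1 -> 5/3
        assert rarefaction_expected([2, 1], 2) == pytest.approx(5 / 3)

    @given(st.lists(st.integers(1, 8), min_size=2, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_subsample_size(self, counts):
        N = sum(counts)
        vals = [rarefaction_expected(counts, n) for n in range(1, N + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bootstrap_interval_brackets_analytic_mean(self, rng):
        counts = [10, 6, 3, 2, 1, 1]
        e, (lo, hi) = rarefaction_expected(counts, 12, bootstrap=300, seed=4)
        assert lo <= e <= hi or abs(e - np.clip(e, lo, hi)) < 0.5


class TestFisher:
    def test_locus_by_region_table_from_the_deme_survey(self):
        # 22/17 H2-Aa vs 13/28 H2-Eb alleles in the two regions
        assert round(fisher_exact_2x2([[22, 17], [13, 28]]), 2) == 0.04

    def test_diagonal_two_by_two(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_five_zero_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_transposition_and_swaps(self, a, b, c, d):
        t = [[a, b], [c, d]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p)
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p)


class TestSampleSizeCorrelation:
    def test_proportional_counts_r2_one(self):
        assert sample_size_correlation([5, 10, 15, 20],
                                       [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_constant_counts_r2_zero(self):
        assert sample_size_correlation([5, 10, 15], [3, 3, 3]) == 0.0

    def test_fixture_matches_closed_form(self):
        x = np.array([6.0, 9, 11, 14, 18])
        y = np.array([3.0, 2, 5, 4, 4])
        r2 = sample_size_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expect = (np.sum(xc * yc) ** 2) / (np.sum(xc ** 2) * np.sum(yc ** 2))
        assert r2 == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sample_size_correlation([5, 5, 5], [1, 2, 3])


class TestDloop:
    def test_single_haplotype_everywhere(self):
        haps = {f"i{k}": ("H1", f"d{k % 2}", f"r{k % 2}") for k in range(6)}
        out = dloop_sharing(haps)
        assert all(v == 1.0 for v in out["modal_fraction"].values())
        assert out["haplotypes_shared_across_regions"] == 1

    def test_all_unique_no_sharing(self):
        haps = {f"i{k}": (f"H{k}", f"d{k}", "r1") for k in range(5)}
        out = dloop_sharing(haps)
        assert out["haplotypes_shared_across_demes"] == 0

    def test_simulator_matrilines_match_truth(self, small_truth):
        out = dloop_sharing({i.id: (i.mtdna, i.deme, i.region)
                             for i in small_truth.individuals})
        # cross-region sharing impossible: haplotype pools are regional
        assert out["haplotypes_shared_across_regions"] == 0
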