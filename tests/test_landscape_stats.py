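import numpy as np
import pytest
from scipy import stats as sps

from introscan.landscape_stats import (
    chromosome_correlation,
    compare_groups,
    gene_overlap,
    nucleotide_diversity,
    random_null,
    telomere_distance,
)


class TestPi:
    def test_monomorphic_zero(self):
        assert nucleotide_diversity(np.zeros((4, 10)), 1000) == 0

    def test_single_site_formula(self):
        # one site at p = 0.5 among 4 haplotypes over 1 kbp
        haps = np.array([[0], [0], [1], [1]])
        expected = (2 * 0.25 * 4 / 3) / 1000
        assert nucleotide_diversity(haps, 1000) == pytest.approx(expected)
        assert expected == pytest.approx(6.667e-4, rel=1e-3)

    def test_relabel_invariant(self, rng):
        m = rng.integers(0, 2, (8, 30))
        assert nucleotide_diversity(m, 500) == pytest.approx(
            nucleotide_diversity(1 - m, 500)
        )

    def test_matches_pairwise_difference_oracle(self, rng):
        # pi is also the mean pairwise hamming distance per bp
        m = rng.integers(0, 2, (6, 25))
        n = m.shape[0]
        total = 0
        pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                total += (m[i] != m[j]).sum()
                pairs += 1
        oracle = total / pairs / 300
        assert nucleotide_diversity(m, 300) == pytest.approx(oracle)

    def test_zero_span_raises(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(np.zeros((4, 1)), 0)


class TestTelomereDistance:
    def test_at_start(self):
        assert telomere_distance(0, 100, 1000) == 0

    def test_symmetric_middle(self):
        assert telomere_distance(400, 600, 1000) == 400

    def test_near_end(self):
        assert telomere_distance(900, 950, 1000) == 50

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            telomere_distance(900, 1100, 1000)


class TestGeneOverlap:
    def test_no_genes(self):
        assert gene_overlap(0, 100, []) == 0

    def test_union_not_double_counted(self):
        assert gene_overlap(0, 100, [(50, 80), (70, 120)]) == 50

    def test_full_cover(self):
        assert gene_overlap(10, 60, [(0, 100)]) == 50


class TestRandomNull:
    def test_replicate_count_and_lengths(self, rng):
        lengths = [100, 250, 30]
        sets = random_null(lengths, {"c1": 1000, "c2": 500}, rng, replicates=100)
        assert len(sets) == 100
        for rep in sets:
            assert sorted(e - s for _, s, e in rep) == sorted(lengths)

    def test_in_bounds(self, rng):
        chrom_lengths = {"c1": 300, "c2": 800}
        for rep in random_null([250, 10], chrom_lengths, rng, replicates=50):
            for chrom, s, e in rep:
                assert 0 <= s < e <= chrom_lengths[chrom]

    def test_too_long_raises(self, rng):
        with pytest.raises(ValueError):
            random_null([2000], {"c1": 1000}, rng)

    def test_mean_telomere_distance_matches_expectation(self, rng):
        # single chromosome length L, window w: start U ~ Uniform[0, L-w],
        # E[min(U, L-w-U)] = (L-w)/4
        L, w = 10_000, 400
        sets = random_null([w] * 20, {"c1": L}, rng, replicates=200)
        d = [telomere_distance(s, e, L) for rep in sets for _, s, e in rep]
        expected = (L - w) / 4
        assert np.mean(d) == pytest.approx(expected, rel=0.05)

    def test_replicates_exchangeable(self, rng):
        sets = random_null([50] * 30, {"c1": 5000}, rng, replicates=60)
        starts_a = [s for rep in sets[:30] for _, s, _ in rep]
        starts_b = [s for rep in sets[30:] for _, s, _ in rep]
        assert sps.ks_2samp(starts_a, starts_b).pvalue > 0.01


class TestCompareGroups:
    def test_identical_groups(self, rng):
        a = rng.lognormal(0, 1, 50)
        res = compare_groups(a, a.copy())
        assert res.cohens_d == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_scale_by_e_gives_unit_d(self, rng):
        # log shift of exactly 1 with log-SD forced to 1
        logs = rng.normal(0, 1, 2000)
        logs = (logs - logs.mean()) / logs.std(ddof=1)
        a = np.exp(logs)
        b = a * np.e
        res = compare_groups(a, b)
        assert res.cohens_d == pytest.approx(1.0, abs=1e-9)

    def test_swap_flips_sign(self, rng):
        a = rng.lognormal(0, 0.5, 40)
        b = rng.lognormal(0.8, 0.5, 60)
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_matches_scipy(self, rng):
        a = rng.lognormal(0, 0.5, 30)
        b = rng.lognormal(0.3, 0.8, 45)
        res = compare_groups(a, b)
        t = sps.ttest_ind(np.log(a), np.log(b), equal_var=False)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_zero_floor_is_half_min_positive(self):
        obs = np.array([0.0, 4.0])
        nul = np.array([2.0, 8.0])
        res = compare_groups(obs, nul)
        # floor = 1.0 -> log(1) = 0 enters the observed group
        assert res.observed_mean_log == pytest.approx((np.log(1.0) + np.log(4.0)) / 2)

    def test_constant_unequal_groups_raise(self):
        with pytest.raises(ValueError):
            compare_groups([2.0, 2.0], [3.0, 3.0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestEndToEndPattern:
    def test_telomere_cd_positive_for_end_biased_regions(self, rng):
        # regions placed at chromosome ends vs uniformly random null:
        # Cd > 0 with observed mean below the null mean
        lengths = {"c1": 2_000_000, "c2": 1_500_000}
        observed = []
        for chrom, L in lengths.items():
            for i, w in enumerate((60_000, 80_000, 50_000)):
                offset = 4_000 * (i + 1)
                observed.append((chrom, offset, offset + w))
                observed.append((chrom, L - w - offset, L - offset))
        obs_tel = [telomere_distance(s, e, lengths[c]) for c, s, e in observed]
        null = random_null([e - s for _, s, e in observed], lengths, rng, replicates=50)
        null_tel = [telomere_distance(s, e, lengths[c]) for rep in null for c, s, e in rep]
        res = compare_groups(obs_tel, null_tel)
        assert res.cohens_d > 0
        assert res.observed_mean_log < res.null_mean_log

    def test_pi_higher_in_introgressed_windows(self, model_w1):
        # recipient-population diversity rises where donor haplotypes entered
        from introscan.scenario_simulator import (
            ScenarioSpec,
            draw_scenario,
            simulate_example,
        )

        rng = np.random.default_rng(23)
        kwargs = dict(region_bp=3e4, window_snps=32, mutation_scale=10.0)
        pis = {"none": [], "ELtoIL": []}
        for label in pis:
            for _ in range(25):
                spec = draw_scenario(label, rng) if label != "none" else ScenarioSpec("none")
                ex = simulate_example(model_w1, spec, (6, 4), rng, **kwargs)
                recipient = ex.alignment.matrix[:12]
                span = int(ex.alignment.positions[-1]) + 1
                pis[label].append(nucleotide_diversity(recipient, span))
        assert np.mean(pis["ELtoIL"]) > np.mean(pis["none"])


class TestChromosomeCorrelation:
    def test_perfect_linear(self):
        lengths = np.array([10, 20, 30, 40, 50.0])
        r, p = chromosome_correlation(2 - 0.01 * lengths, lengths)
        assert r == pytest.approx(-1.0)

    def test_permutation_invariant(self, rng):
        lengths = rng.uniform(10, 100, 8)
        fracs = rng.uniform(0, 1, 8)
        r1, _ = chromosome_correlation(fracs, lengths)
        perm = rng.permutation(8)
        r2, _ = chromosome_correlation(fracs[perm], lengths[perm])
        assert r1 == pytest.approx(r2)

    def test_matches_manual_formula(self):
        x = np.array([1.0, 2, 3, 4, 7])
        y = np.array([2.0, 1, 4, 3, 9])
        r, p = chromosome_correlation(y, x)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual)

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            chromosome_correlation([1, 2], [1, 2])
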