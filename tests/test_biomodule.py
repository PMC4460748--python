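"""Ordered-list overlap, similarity score, permutation null, module extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from biomodules.biomodule import (
    OrderedList,
    expected_overlap_ci,
    extract_biomodule,
    overlap_curve,
    ordered_lists_from_stats,
    permutation_pvalue,
    similarity_score,
)
from biomodules.errors import DataError


def olist(genes):
    genes = list(genes)
    # descending ranks encoded in the values so from_stats preserves order
    return OrderedList.from_stats(genes, np.arange(len(genes), 0, -1), descending=True)


def prefix_overlap_oracle(a, b, n):
    return len(set(a[:n]) & set(b[:n]))


class TestOverlapCurve:
    def test_small_example(self):
        curve = overlap_curve(olist("abc"), olist(["b", "a", "c"]), n_max=3)
        assert list(curve.top) == [0, 2, 3]

    def test_identical_lists(self):
        curve = overlap_curve(olist("abcdef"), olist("abcdef"), n_max=6)
        assert list(curve.top) == [1, 2, 3, 4, 5, 6]
        assert list(curve.bottom) == [1, 2, 3, 4, 5, 6]

    def test_random_lists_match_prefix_oracle(self):
        rng = np.random.default_rng(71)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(25):
            a = list(rng.permutation(genes))
            b = list(rng.permutation(genes))
            curve = overlap_curve(olist(a), olist(b), n_max=50)
            for n in (1, 5, 17, 50):
                assert curve.top[n - 1] == prefix_overlap_oracle(a, b, n)
                assert curve.bottom[n - 1] == prefix_overlap_oracle(a[::-1], b[::-1], n)

    def test_curve_invariants(self):
        rng = np.random.default_rng(72)
        genes = [f"g{i}" for i in range(80)]
        a, b = list(rng.permutation(genes)), list(rng.permutation(genes))
        curve = overlap_curve(olist(a), olist(b))
        assert (np.diff(curve.top) >= 0).all()
        assert (curve.top <= curve.n).all()
        assert curve.top[-1] == 80

    def test_universe_mismatch_reported(self):
        with pytest.raises(DataError, match="x"):
            overlap_curve(olist("abc"), olist("abx"))


class TestExpectedOverlap:
    def test_mean_is_n_squared_over_N(self):
        mean, lo, hi = expected_overlap_ci(100, 10)
        assert mean == pytest.approx(1.0)
        assert lo <= mean <= hi

    def test_degenerate_full_rank(self):
        mean, lo, hi = expected_overlap_ci(30, 30)
        assert (mean, lo, hi) == (30.0, 30.0, 30.0)

    def test_quantiles_match_exact_enumeration(self):
        N, n = 20, 5
        # enumerate the hypergeometric pmf directly
        from math import comb

        pmf = np.array(
            [comb(n, k) * comb(N - n, n - k) / comb(N, n) for k in range(n + 1)]
        )
        cdf = np.cumsum(pmf)
        lo_exact = int(np.searchsorted(cdf, 0.025))
        hi_exact = int(np.searchsorted(cdf, 0.975))
        mean, lo, hi = expected_overlap_ci(N, n)
        assert mean == pytest.approx(n * n / N)
        assert lo == lo_exact
        assert hi == hi_exact


class TestSimilarityScore:
    def test_beta_zero_is_plain_sum(self):
        a, b = olist("abcde"), olist(["b", "a", "e", "c", "d"])
        curve = overlap_curve(a, b, n_max=5)
        score = similarity_score(a, b, beta=0.0, n_max=5)
        assert score["top"] == pytest.approx(curve.top.sum())

    def test_identical_lists_closed_form(self):
        n = 12
        a = olist([f"g{i}" for i in range(n)])
        beta = 0.3
        score = similarity_score(a, a, beta=beta, n_max=n)
        expected = sum(np.exp(-beta * k) * k for k in range(1, n + 1))
        assert score["top"] == pytest.approx(expected)

    def test_ten_gene_hand_summation(self):
        rng = np.random.default_rng(73)
        genes = [f"g{i}" for i in range(10)]
        a, b = list(rng.permutation(genes)), list(rng.permutation(genes))
        beta, n_max = 0.2, 7
        expected = sum(
            np.exp(-beta * n) * prefix_overlap_oracle(a, b, n) for n in range(1, n_max + 1)
        )
        assert similarity_score(olist(a), olist(b), beta=beta, n_max=n_max)["top"] == pytest.approx(
            expected
        )


def exact_permutation_p(a, b, beta, n_max):
    """Enumerate every ordering of b's genes; exact null tail probability."""
    obs = similarity_score(olist(a), olist(b), beta=beta, n_max=n_max)["top"]
    genes = list(b)
    scores = [
        similarity_score(olist(a), olist(perm), beta=beta, n_max=n_max)["top"]
        for perm in itertools.permutations(genes)
    ]
    return np.mean([s >= obs - 1e-12 for s in scores])


class TestPermutation:
    def test_identical_lists_min_p(self):
        a = olist([f"g{i}" for i in range(40)])
        for B in (19, 199):
            res = permutation_pvalue(a, a, B=B, seed=1)
            assert res.empirical_p == pytest.approx(1.0 / (B + 1))

    def test_four_gene_universe_converges_to_exact(self):
        rng = np.random.default_rng(74)
        genes = ["a", "b", "c", "d"]
        a = list(rng.permutation(genes))
        b = list(rng.permutation(genes))
        beta, n_max = 0.25, 4
        p_exact = exact_permutation_p(a, b, beta, n_max)
        B = 10_000
        res = permutation_pvalue(olist(a), olist(b), B=B, beta=beta, n_max=n_max, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.empirical_p - p_exact) <= 3 * se + 2.0 / B

    def test_null_calibration_quick(self):
        # 100 independent null pairs, N=200: rejection at 0.05 near nominal
        rng = np.random.default_rng(75)
        genes = [f"g{i}" for i in range(200)]
        rejections = 0
        for i in range(100):
            a = list(rng.permutation(genes))
            b = list(rng.permutation(genes))
            res = permutation_pvalue(olist(a), olist(b), B=200, n_max=50, seed=1000 + i)
            rejections += res.empirical_p <= 0.05
        assert 0.01 <= rejections / 100 <= 0.12

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(76)
        genes = [f"g{i}" for i in range(100)]
        a, b = olist(rng.permutation(genes)), olist(rng.permutation(genes))
        r1 = permutation_pvalue(a, b, B=100, seed=9)
        r2 = permutation_pvalue(a, b, B=100, seed=9)
        assert r1.empirical_p == r2.empirical_p and r1.score == r2.score


def stats_frame(ce, de, genes):
    df = pd.DataFrame({"ce_r": ce, "de_stat": de}, index=genes)
    df.attrs["seed_gene"] = genes[0]
    return df


class TestExtractBiomodule:
    def test_concordant_stats_fill_module(self):
        rng = np.random.default_rng(81)
        x = rng.normal(size=300)
        df = stats_frame(x, 2 * x + 1, [f"g{i}" for i in range(300)])
        mod = extract_biomodule(df, n_top=50, B=99, seed=3)
        assert len(mod.genes) == 50
        assert mod.similarity.empirical_p == pytest.approx(1.0 / 100)

    def test_anticoncordant_stats_give_empty_module(self):
        rng = np.random.default_rng(82)
        x = rng.normal(size=400)
        df = stats_frame(x, -x, [f"g{i}" for i in range(400)])
        mod = extract_biomodule(df, n_top=40, B=99, seed=3)
        assert len(mod.genes) <= 2

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(83)
        ce = rng.normal(size=250)
        de = rng.normal(size=250)
        genes = [f"g{i}" for i in range(250)]
        m1 = extract_biomodule(stats_frame(ce, de, genes), n_top=60, B=49, seed=2)
        m2 = extract_biomodule(
            stats_frame(np.tanh(ce), np.exp(de), genes), n_top=60, B=49, seed=2
        )
        assert m1.genes == m2.genes
        assert m1.similarity.score == pytest.approx(m2.similarity.score)

    def test_n_top_exceeding_universe_rejected(self):
        df = stats_frame([0.1, 0.2], [1.0, 2.0], ["a", "b"])
        with pytest.raises(DataError):
            extract_biomodule(df, n_top=5, B=9)

    def test_planted_module_recovered(self):
        from biomodules.rankstats import ranked_gene_stats
        from biomodules.synthetic import simulate_expression

        m, truth = simulate_expression(rng_seed=1234)
        stats = ranked_gene_stats(m, truth.seed_gene, "case", "control")
        mod = extract_biomodule(stats, n_top=150, B=500, seed=4)
        truth_set = set(truth.module_genes)
        jaccard = len(mod.genes & truth_set) / len(mod.genes | truth_set)
        assert jaccard > 0.3
        assert mod.similarity.empirical_p < 0.05

    def test_directions_are_separate(self):
        rng = np.random.default_rng(85)
        ce = rng.normal(size=200)
        de = rng.normal(size=200)
        genes = [f"g{i}" for i in range(200)]
        df = stats_frame(ce, de, genes)
        up_ce, up_de = ordered_lists_from_stats(df, "up-positive")
        dn_ce, dn_de = ordered_lists_from_stats(df, "down-negative")
        assert list(up_ce.genes) == list(dn_ce.genes[::-1])
        assert list(up_de.genes) == list(dn_de.genes[::-1])
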