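"""Tests for the sweep-detection statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from mksweep.popgen import (
    HaplotypeSample,
    allele_counts,
    effective_allele_number,
    fst,
    g_heterogeneity,
    identify_swept_alleles,
    ld_significance,
    sequence_diversity,
    sequential_bonferroni,
    sweep_report,
    _wc_theta,
)


def make_sample(columns: dict, sample_id="s", n=None):
    """Build a HaplotypeSample from per-locus allele-copy lists."""
    n = n or len(next(iter(columns.values()))) // 2
    index = pd.MultiIndex.from_product(
        [[f"i{k}" for k in range(n)], [0, 1]], names=["individual", "slot"]
    )
    return HaplotypeSample(sample_id, pd.DataFrame(columns, index=index))


class TestAlleleCounts:
    def test_fully_genotyped_sample_has_2n_copies(self):
        s = make_sample({"L": ["x"] * 60 + ["y"] * 36})
        assert allele_counts(s, "L").sum() == 96

    def test_missing_slot_reduces_count(self):
        col = ["x"] * 95 + [np.nan]
        s = make_sample({"L": col})
        assert allele_counts(s, "L").sum() == 95

    def test_empty_locus_warns(self):
        s = make_sample({"L": [np.nan] * 4})
        with pytest.warns(UserWarning):
            counts = allele_counts(s, "L")
        assert counts.sum() == 0

    def test_unknown_locus_raises(self):
        s = make_sample({"L": ["x", "x"]})
        with pytest.raises(KeyError):
            allele_counts(s, "M")


class TestGTest:
    def test_identical_distributions_are_homogeneous(self):
        res = g_heterogeneity(
            pd.Series([10, 20, 30]), pd.Series([20, 40, 60]), method="asymptotic"
        )
        assert res.g == 0.0
        assert res.p_asymptotic == 1.0

    def test_disjoint_two_by_two_table(self):
        res = g_heterogeneity(
            pd.Series([10, 0]), pd.Series([0, 10]), method="asymptotic"
        )
        assert res.g == pytest.approx(2 * 20 * np.log(2), abs=1e-9)  # 27.726
        assert res.p_asymptotic < 0.001

    def test_invariant_under_column_permutation(self):
        a = pd.Series([5, 12, 3, 9], index=list("wxyz"))
        b = pd.Series([9, 2, 10, 4], index=list("wxyz"))
        g1 = g_heterogeneity(a, b, method="asymptotic").g
        perm = list("zxwy")
        g2 = g_heterogeneity(a[perm], b[perm], method="asymptotic").g
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_monte_carlo_matches_exact_enumeration(self):
        # 2x2 with small fixed margins: enumerate all tables with the
        # hypergeometric distribution as the exact conditional null
        a = pd.Series([8, 4])
        b = pd.Series([3, 9])
        res = g_heterogeneity(a, b, method="both", n_resamples=4000, seed=5)
        r1, c1, n = 12, 11, 24
        p_exact = 0.0
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            table = np.array([[k, r1 - k], [c1 - k, n - r1 - c1 + k]])
            g = g_heterogeneity(
                pd.Series(table[0]), pd.Series(table[1]), method="asymptotic"
            ).g
            if g >= res.g - 1e-12:
                p_exact += hypergeom.pmf(k, n, r1, c1)
        sd = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_monte_carlo - p_exact) < 3 * sd + 1 / 4001

    def test_monte_carlo_is_deterministic_under_seed(self):
        a, b = pd.Series([8, 4, 2]), pd.Series([3, 9, 5])
        p1 = g_heterogeneity(a, b, n_resamples=500, seed=9).p_monte_carlo
        p2 = g_heterogeneity(a, b, n_resamples=500, seed=9).p_monte_carlo
        assert p1 == p2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            g_heterogeneity(pd.Series([0, 0]), pd.Series([3, 4]), method="asymptotic")

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=2, max_size=6
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_g_zero_iff_profiles_identical(self, counts):
        a = pd.Series([c[0] for c in counts], dtype=float)
        b = pd.Series([c[1] for c in counts], dtype=float)
        if a.sum() == 0 or b.sum() == 0 or (a + b > 0).sum() < 2:
            return
        res = g_heterogeneity(a, b, method="asymptotic")
        keep = (a + b) > 0
        identical = np.allclose(
            (a[keep] / a.sum()).to_numpy(), (b[keep] / b.sum()).to_numpy()
        )
        assert res.g >= 0
        assert (res.g < 1e-9) == identical


class TestSweptAlleles:
    def test_single_swept_allele_restores_homogeneity(self):
        pre = pd.Series([10, 30, 30, 20, 10], index=list("abcde"), dtype=float)
        post = pd.Series([60, 13, 13, 9, 5], index=list("abcde"), dtype=float)
        res = identify_swept_alleles(pre, post, alpha=0.05)
        assert res.swept_alleles == ["a"]
        assert res.homogeneous_after_removal
        # direct recomputation: without the swept allele the G test passes
        sub = list("bcde")
        assert (
            g_heterogeneity(pre[sub], post[sub], method="asymptotic").p_asymptotic
            >= 0.05
        )

    def test_two_independently_inflated_alleles_need_two_rounds(self):
        pre = pd.Series([30, 25, 20, 15, 10], index=list("abcde"), dtype=float)
        post = pd.Series([45, 8, 30, 10, 7], index=list("abcde"), dtype=float)
        res = identify_swept_alleles(pre, post, alpha=0.05)
        assert res.swept_alleles == ["a", "c"]
        assert res.homogeneous_after_removal

    def test_every_swept_allele_increased_in_frequency(self):
        pre = pd.Series([10, 30, 30, 20, 10], index=list("abcde"), dtype=float)
        post = pd.Series([60, 13, 13, 9, 5], index=list("abcde"), dtype=float)
        res = identify_swept_alleles(pre, post, alpha=0.05)
        for allele in res.swept_alleles:
            assert post[allele] / post.sum() > pre[allele] / pre.sum()

    def test_homogeneous_input_is_a_precondition_violation(self):
        with pytest.raises(ValueError, match="homogeneous"):
            identify_swept_alleles(
                pd.Series([10, 10, 10]), pd.Series([10, 10, 10]), alpha=0.05
            )

    def test_two_allele_locus_not_applicable(self):
        with pytest.raises(ValueError, match="3 alleles"):
            identify_swept_alleles(pd.Series([50, 10]), pd.Series([10, 50]))

    def test_removing_identified_allele_never_increases_g(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pre = pd.Series(rng.integers(1, 40, size=5).astype(float))
            post = pre.copy()
            post.iloc[0] += 60  # force heterogeneity via one rising allele
            g_full = g_heterogeneity(pre, post, method="asymptotic").g
            res = identify_swept_alleles(pre, post, alpha=0.05)
            first = res.swept_alleles[0]
            rest = [a for a in pre.index if a != first]
            g_rest = g_heterogeneity(pre[rest], post[rest], method="asymptotic").g
            assert g_rest <= g_full + 1e-9


class TestFst:
    def test_identical_distributions_give_null_fst(self):
        # the unbiased variance-components estimator is slightly negative
        # (about -1/(n-1)) when the two samples coincide exactly
        a = pd.Series([48, 48])
        res = fst(a, a, n_resamples=200, seed=1)
        assert res.theta == pytest.approx(0.0, abs=0.02)
        assert res.p_permutation > 0.5

    def test_fixed_alternative_alleles_give_maximal_fst(self):
        res = fst(pd.Series([500, 0]), pd.Series([0, 500]), n_resamples=99, seed=1)
        assert res.theta == pytest.approx(1.0, abs=1e-3)
        assert res.p_permutation == pytest.approx(0.01, abs=0.001)

    def test_estimator_matches_longhand_variance_components(self):
        # counts [[60, 36], [30, 66]], evaluated symbol by symbol
        c = np.array([[60.0, 36.0], [30.0, 66.0]])
        n1, n2 = 96.0, 96.0
        ntot = n1 + n2
        p1, p2 = c[0] / n1, c[1] / n2
        pbar = c.sum(axis=0) / ntot
        nc = (ntot - (n1**2 + n2**2) / ntot) / 1
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        sa = (msp - msg) / nc
        expected = sa.sum() / (sa + msg).sum()
        assert _wc_theta(c) == pytest.approx(expected, abs=1e-12)
        assert _wc_theta(c) == pytest.approx(0.16992481203007517, abs=1e-12)

    def test_pooled_monomorphic_locus_flagged(self):
        res = fst(pd.Series({"x": 96}), pd.Series({"x": 90}))
        assert res.monomorphic
        assert np.isnan(res.theta)

    def test_permutation_null_is_calibrated(self):
        # under the null (copies exchangeable) the permutation p-value
        # rejects at close to its nominal rate
        rng = np.random.default_rng(12)
        rej = 0
        reps = 200
        for _ in range(reps):
            pool = rng.multinomial(192, [0.5, 0.3, 0.2])
            copies = np.repeat(np.arange(3), pool)
            rng.shuffle(copies)
            c1 = np.bincount(copies[:96], minlength=3)
            c2 = np.bincount(copies[96:], minlength=3)
            p = fst(pd.Series(c1), pd.Series(c2), n_resamples=99, seed=rng).p_permutation
            rej += p <= 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert rej / reps < 0.05 + 3 * sd


class TestDiversity:
    def test_effective_allele_number_examples(self):
        assert effective_allele_number([0.25] * 4) == pytest.approx(4.0)
        assert effective_allele_number([1.0]) == pytest.approx(1.0)
        assert effective_allele_number([0.5, 0.25, 0.25]) == pytest.approx(
            1 / 0.375, abs=1e-12
        )

    def test_effective_alleles_bounded_by_observed_and_shrink_under_inflation(self):
        p = np.array([0.3, 0.3, 0.2, 0.2])
        assert effective_allele_number(p) <= len(p)
        inflated = np.array([0.7, 0.3 * 0.3, 0.2 * 0.3, 0.2 * 0.3 + 0.3 * 0.3 * 0])
        inflated = inflated / inflated.sum()
        assert effective_allele_number(inflated) < effective_allele_number(p)

    def test_identical_sequences_have_no_diversity(self):
        d = sequence_diversity(["ACGT" * 25], counts=[6])
        assert d.pi == 0 and d.s_sites == 0 and d.hd == 0
        assert np.isnan(d.tajima_d)

    def test_two_haplotypes_one_snp(self):
        # two haplotypes differing at 1 of 100 sites, two copies each:
        # k = 4 differing pairs / 6 pairs, pi = k / 100
        d = sequence_diversity(["A" * 100, "C" + "A" * 99], counts=[2, 2])
        assert d.k_avg == pytest.approx(2 * 2 / 6, abs=1e-12)
        assert d.pi == pytest.approx((2 * 2 / 6) / 100, abs=1e-12)
        assert d.hd == pytest.approx(4 / 3 * 0.5, abs=1e-12)

    def test_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        haps = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(5)]
        counts = [3, 2, 2, 1, 1]
        d = sequence_diversity(haps, counts)
        expanded = [h for h, c in zip(haps, counts) for _ in range(c)]
        diffs = [
            sum(a != b for a, b in zip(expanded[i], expanded[j]))
            for i in range(len(expanded))
            for j in range(i + 1, len(expanded))
        ]
        assert d.k_avg == pytest.approx(np.mean(diffs), abs=1e-9)
        assert d.pi == pytest.approx(np.mean(diffs) / 40, abs=1e-9)

    def test_tajimas_d_matches_independent_formula(self):
        seqs = ["AAAAA", "AAAAT", "AATAT", "CATAT", "CATAA", "CGTGA"]
        d = sequence_diversity(seqs)
        n, s = 6, d.s_sites
        assert s == 5
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (d.k_avg - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
        assert d.tajima_d == pytest.approx(expected, abs=1e-9)

    def test_gap_columns_excluded(self):
        with_gap = ["A-CT", "ATCT", "ATCA"]
        d = sequence_diversity(with_gap)
        assert d.n_sites == 3  # the gapped column is dropped entirely
        assert d.s_sites == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sequence_diversity(["ACGT", "ACG"])


class TestLdSignificance:
    def test_perfect_association_is_highly_significant(self):
        col_a = ["x"] * 50 + ["y"] * 50
        col_b = ["u"] * 50 + ["v"] * 50
        s = make_sample({"A": col_a, "B": col_b})
        res = ld_significance(s, "A", "B", n_resamples=2999, seed=2)
        assert res.p < 0.001

    def test_monomorphic_locus_not_applicable(self):
        s = make_sample({"A": ["x"] * 20, "B": ["u", "v"] * 10})
        res = ld_significance(s, "A", "B", seed=1)
        assert res.monomorphic and res.p is None

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        s = make_sample(
            {"A": rng.choice(list("xyz"), 60), "B": rng.choice(list("uv"), 60)}
        )
        p1 = ld_significance(s, "A", "B", n_resamples=299, seed=4).p
        p2 = ld_significance(s, "A", "B", n_resamples=299, seed=4).p
        assert p1 == p2

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(21)
        rej, reps = 0, 150
        for _ in range(reps):
            s = make_sample(
                {
                    "A": rng.choice(list("wxyz"), 96),
                    "B": rng.choice(list("uvst"), 96),
                }
            )
            p = ld_significance(s, "A", "B", n_resamples=99, seed=rng).p
            rej += p <= 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * sd + 0.01


class TestSequentialBonferroni:
    def test_holm_stepdown_examples(self):
        assert sequential_bonferroni([0.001, 0.04], 0.05).tolist() == [True, True]
        assert sequential_bonferroni([0.03, 0.04], 0.05).tolist() == [False, False]
        assert sequential_bonferroni([], 0.05).tolist() == []

    def test_holm_no_less_powerful_than_bonferroni(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = rng.uniform(0, 0.2, size=8)
            holm = sequential_bonferroni(p, 0.05)
            bonf = p < 0.05 / len(p)
            assert (holm | ~bonf).all()  # every Bonferroni rejection survives

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])


class TestSweepReport:
    def test_sample_compared_with_itself_is_null(self, sweep_pair):
        pre, _, _ = sweep_pair
        rep = sweep_report(
            pre, pre, alpha=0.05, seed=31, n_resamples=200, compute_ld=False
        )
        assert not rep.per_locus["holm_reject"].any()
        # estimator bias for coinciding samples is about -1/(n-1)
        assert (rep.per_locus["fst"].abs().dropna() < 0.02).all()

    def test_sweep_detected_on_linked_but_not_unlinked_loci(self, panel, sweep_pair):
        pre, post, _ = sweep_pair
        rep = sweep_report(
            pre, post, alpha=0.05, seed=32, n_resamples=1000, compute_ld=False
        )
        linked = rep.per_locus.loc[panel.linked_markers]
        unlinked = rep.per_locus.loc[panel.unlinked_markers]
        assert linked["holm_reject"].sum() >= 10
        assert unlinked["holm_reject"].sum() == 0
        # novel immigrant alleles flagged as migration candidates
        flagged = set(rep.per_locus.index[rep.per_locus["novel_alleles"] != ""])
        assert set(panel.table.index[panel.table["novel"]]) <= flagged

    def test_disjoint_locus_sets_signalled(self, sweep_pair):
        pre, post, _ = sweep_pair
        with pytest.raises(ValueError, match="absent"):
            sweep_report(pre, post, panel=["nope"], seed=1)
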