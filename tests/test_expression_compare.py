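"""Normalisation, NB Wald test, BH, overlaps and class comparisons."""

import numpy as np
import pytest
from scipy import stats

from paskit.models import CountMatrix
from paskit.expression_compare import (
    DEResult,
    bh_adjust,
    classify_cold_responsive,
    compare_gene_classes,
    estimate_size_factors,
    match_induction_pattern,
    overlap_de,
)
from paskit.expression_compare import test_differential as nb_wald_test


def _cm(counts, conditions, gene_ids=None):
    counts = np.asarray(counts)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        conditions=conditions,
    )


class TestSizeFactors:
    def test_doubled_sample_hand_computed(self):
        # geometric-mean reference gives ratios 1/sqrt(2) and sqrt(2)
        m = _cm([[10, 20], [30, 60], [50, 100]], ["a", "b"])
        np.testing.assert_allclose(
            estimate_size_factors(m), [0.70710678, 1.41421356], rtol=1e-6
        )

    def test_identical_samples_unity(self):
        m = _cm([[10, 10, 10], [5, 5, 5]], ["a", "a", "b"])
        np.testing.assert_allclose(estimate_size_factors(m), 1.0)

    def test_single_sample_unity(self):
        m = _cm([[7], [3]], ["a"])
        np.testing.assert_allclose(estimate_size_factors(m), 1.0)

    def test_no_universally_expressed_gene_errors(self):
        m = _cm([[0, 5], [5, 0]], ["a", "b"])
        with pytest.raises(ValueError):
            estimate_size_factors(m)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        def brute(p):
            n = len(p)
            out = []
            for i, pi in enumerate(p):
                # smallest step-up bound over all ranks >= rank of pi
                vals = [
                    sorted(p)[k] * n / (k + 1)
                    for k in range(len(p))
                    if sorted(p)[k] >= pi
                ]
                out.append(min(1.0, min(vals)))
            return out

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            np.testing.assert_allclose(ours, brute(list(p)), atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_many_random_vectors_vs_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(size=20)
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestDifferential:
    def test_log2fc_with_pseudocount(self):
        counts = np.vstack(
            [[10, 10, 10, 80, 80, 80], [100, 100, 100, 100, 100, 100]]
        )
        m = _cm(counts, ["a"] * 3 + ["b"] * 3)
        m.size_factors = np.ones(6)
        res = nb_wald_test(m, "a", "b")
        assert res[0].log2fc == pytest.approx(np.log2(80.5 / 10.5), abs=1e-9)

    def test_all_zero_gene_is_uninformative(self):
        counts = np.vstack([[0] * 6, [50, 60, 55, 52, 58, 54]])
        m = _cm(counts, ["a"] * 3 + ["b"] * 3)
        res = nb_wald_test(m, "a", "b")
        assert res[0].call == "nonDE" and res[0].p == 1.0

    def test_missing_condition_errors(self):
        m = _cm([[1, 2, 3, 4]], ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            nb_wald_test(m, "a", "c")

    def test_scaling_invariance(self):
        """Scaling one sample's counts and its size factor leaves log2fc fixed."""
        rng = np.random.default_rng(8)
        counts = rng.poisson(50, size=(100, 6))
        m1 = _cm(counts, ["a"] * 3 + ["b"] * 3)
        estimate_size_factors(m1)
        res1 = nb_wald_test(m1, "a", "b")

        scaled = counts.astype(float).copy()
        scaled[:, 0] *= 4
        m2 = _cm(scaled.astype(int), ["a"] * 3 + ["b"] * 3)
        m2.size_factors = m1.size_factors.copy()
        m2.size_factors[0] *= 4
        res2 = nb_wald_test(m2, "a", "b")
        for r1, r2 in zip(res1, res2):
            assert r1.log2fc == pytest.approx(r2.log2fc, abs=1e-9)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(12)
        rates = []
        for lfc in (0.5, 1.0, 2.0):
            hits = 0
            n = 300
            mu_a = 100.0
            mu_b = mu_a * 2**lfc
            r = 1 / 0.05
            counts = np.hstack(
                [
                    rng.negative_binomial(r, r / (r + mu_a), size=(n, 3)),
                    rng.negative_binomial(r, r / (r + mu_b), size=(n, 3)),
                ]
            )
            m = _cm(counts, ["a"] * 3 + ["b"] * 3)
            m.size_factors = np.ones(6)
            res = nb_wald_test(m, "a", "b")
            rates.append(np.mean([x.call == "UP" for x in res]))
        assert rates[0] <= rates[1] <= rates[2]


class TestOverlapAndPatterns:
    @staticmethod
    def _de(rows):
        return [
            DEResult(g, lfc, 0.001 if call != "nonDE" else 0.9,
                     0.01 if call != "nonDE" else 0.95, call)
            for g, lfc, call in rows
        ]

    def test_up_intersection_counts(self):
        a = self._de([("g1", 1, "UP"), ("g2", 1, "UP"), ("g3", 1, "UP")])
        b = self._de([("g2", 2, "UP"), ("g3", 2, "UP"), ("g4", 2, "UP")])
        s = overlap_de(a, b)
        assert s.n_up_both == 2 and s.n_down_both == 0

    def test_identical_tables_correlate_perfectly(self):
        a = self._de([("g1", 0.8, "UP"), ("g2", 2.0, "UP"), ("g3", -1.0, "DOWN")])
        s = overlap_de(a, a)
        assert s.fc_correlation == pytest.approx(1.0)

    def test_disjoint_calls_give_null_correlation(self):
        a = self._de([("g1", 1, "UP")])
        b = self._de([("g2", 1, "UP")])
        s = overlap_de(a, b)
        assert s.n_up_both == 0 and s.fc_correlation is None

    def test_match_induction_pattern(self):
        early = self._de([("g1", 1, "UP"), ("g2", 1, "UP"), ("g3", 1, "nonDE")])
        late = self._de([("g1", -1, "DOWN"), ("g2", 1, "UP"), ("g3", -1, "DOWN")])
        assert match_induction_pattern(early, late) == ["g1"]

    def test_classify_cold_responsive(self):
        t1 = self._de([("g1", 1, "UP"), ("g2", 0, "nonDE")])
        t2 = self._de([("g1", 0, "nonDE"), ("g2", 0, "nonDE")])
        out = classify_cold_responsive([t1, t2])
        assert out == {"g1": True, "g2": False}


class TestMannWhitney:
    def test_separated_samples_exact(self):
        vals = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 4.0, "b2": 5.0, "b3": 6.0}
        u, p = compare_gene_classes(vals, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_symmetric_samples_centre_u(self):
        vals = {f"a{i}": float(i) for i in range(6)}
        vals.update({f"b{i}": float(i) + 0.5 for i in range(6)})
        u, p = compare_gene_classes(
            vals, [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]
        )
        assert abs(u - 18.0) <= 3.0 and p > 0.5

    def test_exact_and_asymptotic_agree(self):
        """At n=8 the normal approximation tracks the exact enumeration."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=8)
            vals = {f"a{i}": v for i, v in enumerate(a)}
            vals.update({f"b{i}": v for i, v in enumerate(b)})
            ga, gb = list(vals)[:8], list(vals)[8:]
            _, p_exact = compare_gene_classes(vals, ga, gb)
            p_asym = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.02
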