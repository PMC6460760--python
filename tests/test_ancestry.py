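"""Hybrid index, interspecific heterozygosity and class assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridzone.ancestry import (
    ClassThresholds,
    HybridClass,
    classify_hybrid,
    counting_hybrid_index,
    interspecific_heterozygosity,
    ml_hybrid_index,
    polarize,
    _loglik_terms,
)
from hybridzone.datamodel import MISSING, Group

from conftest import A, B, H, make_matrix

M = MISSING


def freq_table(pairs):
    return pd.DataFrame(
        {"p_a": [p for p, _ in pairs], "p_b": [q for _, q in pairs]},
        index=pd.Index([f"L{i:03d}" for i in range(len(pairs))], name="locus_id"),
    )


def grid_argmax(calls, freqs):
    """Independent brute-force oracle: argmax over a fine grid of h."""
    grid = np.linspace(0.0, 1.0, 10001)
    calls = np.asarray(calls)
    keep = calls != MISSING
    g = calls[keep].astype(float)
    p_a = freqs["p_a"].to_numpy(float)[keep]
    p_b = freqs["p_b"].to_numpy(float)[keep]
    lls = [np.sum(_loglik_terms(h, g, p_a, p_b)) for h in grid]
    return grid[int(np.argmax(lls))]


class TestPolarize:
    def test_flip_rules(self):
        m = make_matrix(
            [[0, 0, 0], [2, 2, 2], [1, 0, 2]], groups=[A, B, H]
        )
        freqs = pd.DataFrame(
            {
                "p_a": [0.0, 1.0, 0.9],
                "p_b": [1.0, 0.0, 0.05],
                "n_a": 10, "n_b": 10,
            },
            index=pd.Index(m.locus_ids, name="locus_id"),
        )
        pol, pf = polarize(m, freqs, m.locus_ids)
        # locus 0: alt already B-associated, unchanged
        np.testing.assert_array_equal(pol.calls[:, 0], [0, 2, 1])
        # locus 1: p_b(alt)=0 -> flip
        np.testing.assert_array_equal(pol.calls[:, 1], [2, 0, 2])
        # locus 2: p_a=0.9 > p_b=0.05 -> B-associated allele is ref -> flip
        np.testing.assert_array_equal(pol.calls[:, 2], [2, 0, 0])
        assert pf.loc["L002", "p_a"] == pytest.approx(0.1)
        assert pf.loc["L002", "p_b"] == pytest.approx(0.95)

    def test_equal_frequencies_cannot_polarize(self):
        m = make_matrix([[0], [2]], groups=[A, B])
        freqs = pd.DataFrame(
            {"p_a": [0.5], "p_b": [0.5], "n_a": 10, "n_b": 10},
            index=pd.Index(["L000"], name="locus_id"),
        )
        with pytest.raises(ValueError, match="p_A == p_B"):
            polarize(m, freqs, ["L000"])


class TestHybridIndex:
    def test_closed_form_at_fixed_loci(self):
        """At diagnostic loci the MLE equals the allele-counting estimator."""
        freqs = freq_table([(0.0, 1.0)] * 20)
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = rng.integers(0, 3, size=20)
            h, _, _ = ml_hybrid_index(calls, freqs)
            assert h == pytest.approx(counting_hybrid_index(calls), abs=1e-9)

    def test_pure_and_f1_extremes(self):
        freqs = freq_table([(0.0, 1.0)] * 10)
        assert ml_hybrid_index(np.zeros(10, int), freqs)[0] == 0.0
        assert ml_hybrid_index(np.full(10, 2), freqs)[0] == 1.0
        assert ml_hybrid_index(np.ones(10, int), freqs)[0] == pytest.approx(
            0.5, abs=1e-9
        )

    def test_matches_grid_search_oracle(self):
        freqs = freq_table([(0.1, 0.9), (0.2, 0.9)])
        calls = np.array([2, 1])
        h, _, _ = ml_hybrid_index(calls, freqs)
        assert h == pytest.approx(grid_argmax(calls, freqs), abs=1e-3)

        rng = np.random.default_rng(5)
        for _ in range(10):
            pairs = [
                (p, min(p + d, 1.0))
                for p, d in zip(rng.uniform(0, 0.3, 6), rng.uniform(0.3, 0.9, 6))
            ]
            freqs = freq_table(pairs)
            calls = rng.integers(0, 3, size=6)
            h, _, _ = ml_hybrid_index(calls, freqs)
            assert h == pytest.approx(grid_argmax(calls, freqs), abs=1e-3)

    def test_support_interval_brackets_estimate(self):
        freqs = freq_table([(0.0, 1.0)] * 30)
        calls = np.array([1] * 15 + [2] * 10 + [0] * 5)
        h, lo, hi = ml_hybrid_index(calls, freqs)
        assert lo < h < hi
        # the interval endpoints sit 2 lnL units below the maximum
        g = calls.astype(float)
        pa = freqs["p_a"].to_numpy()
        pb = freqs["p_b"].to_numpy()
        ln = lambda x: np.sum(_loglik_terms(x, g, pa, pb))
        assert ln(h) - ln(lo) == pytest.approx(2.0, abs=1e-6)

    def test_invariant_to_locus_order_and_missing(self):
        freqs = freq_table([(0.05, 0.95), (0.1, 0.8), (0.0, 1.0), (0.2, 0.9)])
        calls = np.array([1, 2, 0, 1])
        h0, _, _ = ml_hybrid_index(calls, freqs)
        order = [2, 0, 3, 1]
        h1, _, _ = ml_hybrid_index(calls[order], freqs.iloc[order])
        assert h1 == pytest.approx(h0, abs=1e-12)
        # a missing locus is the same as dropping it
        calls_m = np.array([1, 2, M, 1])
        h2, _, _ = ml_hybrid_index(calls_m, freqs)
        h3, _, _ = ml_hybrid_index(calls[[0, 1, 3]], freqs.iloc[[0, 1, 3]])
        assert h2 == pytest.approx(h3, abs=1e-12)

    def test_all_missing_is_undefined(self):
        freqs = freq_table([(0.0, 1.0)])
        with pytest.raises(ValueError, match="missing"):
            ml_hybrid_index(np.array([M]), freqs)


class TestHeterozygosity:
    def test_counting(self):
        assert interspecific_heterozygosity(np.ones(8, int)) == 1.0
        assert interspecific_heterozygosity(np.zeros(8, int)) == 0.0
        assert interspecific_heterozygosity(np.full(8, 2)) == 0.0
        assert interspecific_heterozygosity(np.array([1, 1, 0, 2, M])) == 0.5

    def test_triangle_constraint_at_fixed_loci(self, fixed_panel_dataset):
        """H <= 2 min(h, 1-h): the triangle plot's feasible region."""
        from hybridzone.filtering import (
            allele_freq_differential, estimate_parental_freqs,
            select_differentiated,
        )

        data = fixed_panel_dataset
        freqs = estimate_parental_freqs(data.matrix)
        diff = allele_freq_differential(freqs)
        ids = select_differentiated(diff, 1.0)
        pol, pf = polarize(data.matrix, freqs, ids)
        for i in range(pol.n_samples):
            calls = pol.calls[i]
            if (calls != M).sum() == 0:
                continue
            h = counting_hybrid_index(calls)
            het = interspecific_heterozygosity(calls)
            assert het <= 2 * min(h, 1 - h) + 1e-12


class TestClassification:
    @pytest.mark.parametrize(
        "h,het,expected",
        [
            (0.5, 0.9, HybridClass.F1),
            (0.1, 0.2, HybridClass.BACKCROSS_A),
            (1.0, 0.0, HybridClass.PURE_B),
            (0.0, 0.0, HybridClass.PURE_A),
            (0.5, 0.3, HybridClass.MULTIGEN),
            (0.25, 0.3, HybridClass.BACKCROSS_A),  # boundary -> backcross
            (0.75, 0.3, HybridClass.BACKCROSS_B),
            (0.9, 0.5, HybridClass.BACKCROSS_B),
        ],
    )
    def test_rules(self, h, het, expected):
        cls, _ = classify_hybrid(h, het)
        assert cls == expected

    def test_extreme_h_with_high_het_is_flagged_f1(self):
        cls, boundary = classify_hybrid(0.1, 0.95)
        assert cls == HybridClass.F1 and boundary

    def test_partition_is_total_on_unit_square_grid(self):
        """Every (h, H) on a 101 x 101 grid maps to exactly one class."""
        for h in np.linspace(0, 1, 101):
            for het in np.linspace(0, 1, 101):
                cls, _ = classify_hybrid(round(h, 2), round(het, 2))
                assert isinstance(cls, HybridClass)


class TestParameterRecovery:
    def test_pedigree_means(self):
        """F1 mean h is exactly 0.5; BC1->B and F2 means match pedigree
        expectations within 3 Monte-Carlo standard errors."""
        from hybridzone.filtering import (
            allele_freq_differential, estimate_parental_freqs,
            select_differentiated,
        )
        from hybridzone.simulate import SimConfig, simulate_dataset
        from hybridzone.ancestry import estimate_ancestry

        config = SimConfig(
            seed=77, n_loci=50, frac_fixed=1.0, frac_high=0.0,
            n_parental_a=25, n_parental_b=25,
            class_counts={"F1": 60, "F2": 70, "BC1_B": 70},
            missing_rate=0.0,
        )
        data = simulate_dataset(config)
        freqs = estimate_parental_freqs(data.matrix)
        ids = select_differentiated(allele_freq_differential(freqs), 1.0)
        pol, pf = polarize(data.matrix, freqs, ids)
        anc = estimate_ancestry(pol, pf).merge(
            data.truth, on="sample_id"
        )
        f1 = anc[anc.pedigree_class == "F1"]
        assert (f1["h"] == 0.5).all()

        bc = anc[anc.pedigree_class == "BC1_B"]
        se = np.sqrt(50 * 0.25) / 100 / np.sqrt(len(bc))
        assert abs(bc["h"].mean() - 0.75) <= 3 * se

        f2 = anc[anc.pedigree_class == "F2"]
        se_het = np.sqrt(0.25 / 50) / np.sqrt(len(f2))
        assert abs(f2["het"].mean() - 0.5) <= 3 * se_het
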