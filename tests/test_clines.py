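"""Genomic cline fitting, neutral model, bootstrap p-values and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridzone.clines import (
    bh_adjust,
    by_alpha,
    cline_significance,
    deviation_summary,
    fit_multinomial_cline,
    neutral_loglik,
)
from hybridzone.datamodel import MISSING


class TestNeutralLoglik:
    def test_single_term_closed_forms(self):
        # fixed locus, h = 0.5, heterozygote: Binomial(2, 0.5) -> log 0.5
        assert neutral_loglik(
            np.array([1]), np.array([0.5]), 0.0, 1.0
        ) == pytest.approx(np.log(0.5))
        # h = 0, AA at a fixed locus: probability 1
        assert neutral_loglik(np.array([0]), np.array([0.0]), 0.0, 1.0) == 0.0

    def test_matches_direct_summation_on_toy(self):
        calls = np.array([0, 1, 2, 1, MISSING])
        h = np.array([0.1, 0.4, 0.9, 0.5, 0.7])
        p_a, p_b = 0.05, 0.95
        expected = 0.0
        for g, hi in zip(calls, h):
            if g == MISSING:
                continue
            q = hi * p_b + (1 - hi) * p_a
            p = [(1 - q) ** 2, 2 * q * (1 - q), q**2][g]
            expected += np.log(p)
        assert neutral_loglik(calls, h, p_a, p_b) == pytest.approx(expected)

    def test_impossible_genotype_floored_with_warning(self):
        with pytest.warns(UserWarning, match="impossible"):
            ll = neutral_loglik(np.array([2]), np.array([0.0]), 0.0, 1.0)
        assert ll == pytest.approx(np.log(1e-12))


class TestMultinomialFit:
    def test_loglik_matches_statsmodels_mnlogit(self):
        """Independent ML oracle on a 12-sample toy (no separation)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        h = np.linspace(0.05, 0.95, 12)
        g = np.array([0, 1, 0, 2, 1, 1, 0, 2, 1, 2, 2, 1])
        fit = fit_multinomial_cline(g, h)
        X = sm.add_constant(h)
        ref = sm.MNLogit(g, X).fit(disp=0, method="newton")
        assert fit.lnl_fit == pytest.approx(ref.llf, abs=1e-4)

    def test_no_signal_gives_near_zero_lr(self):
        """Genotypes drawn ignoring h: the cline adds nothing over a neutral
        model with the matching marginal frequency."""
        rng = np.random.default_rng(4)
        n = 80
        h = rng.uniform(0, 1, n)
        q0 = 0.5
        g = rng.binomial(2, q0, size=n)
        # neutral model with flat q equal to the marginal
        p = g.mean() / 2
        lnl_neutral = neutral_loglik(g, np.full(n, 0.5), p, p)
        fit = fit_multinomial_cline(g, h, lnl_neutral=lnl_neutral)
        # the 4-parameter cline should add only chance improvement over the
        # matched flat model (LR below the chi2_3 99th percentile)
        assert fit.lr < 11.35

    def test_lr_nonnegative_under_own_neutral_model(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            r = np.random.default_rng(seed)
            h = r.uniform(0, 1, 40)
            g = r.binomial(2, h)
            fit = fit_multinomial_cline(g, h, p_a=0.0, p_b=1.0)
            assert fit.lr >= -1e-6

    def test_fitted_probabilities_normalized(self):
        rng = np.random.default_rng(11)
        h = rng.uniform(0, 1, 30)
        g = rng.binomial(2, h)
        fit = fit_multinomial_cline(g, h, p_a=0.0, p_b=1.0)
        b, c = fit.coefficients[:2], fit.coefficients[2:]
        eta1 = b[0] + b[1] * h
        eta2 = c[0] + c[1] * h
        z = 1 + np.exp(eta1) + np.exp(eta2)
        probs = np.stack([1 / z, np.exp(eta1) / z, np.exp(eta2) / z])
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            fit_multinomial_cline(np.array([0, 1]), np.array([0.1, 0.9]))
        with pytest.raises(ValueError, match="vary"):
            fit_multinomial_cline(
                np.array([0, 1, 2]), np.array([0.5, 0.5, 0.5])
            )

    def test_complete_separation_is_clipped_not_fatal(self):
        h = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        g = np.array([0, 0, 0, 2, 2, 2])
        fit = fit_multinomial_cline(g, h, p_a=0.0, p_b=1.0)
        assert fit.clipped
        assert np.all(np.abs(fit.coefficients) <= 30 + 1e-9)


class TestSignificance:
    def test_p_bounded_below_and_reproducible(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0.1, 0.9, 30)
        g = rng.binomial(2, h)
        fit = fit_multinomial_cline(g, h, p_a=0.0, p_b=1.0)
        p1, _ = cline_significance(fit, g, h, 0.0, 1.0, n_sims=100, seed=5)
        p2, _ = cline_significance(fit, g, h, 0.0, 1.0, n_sims=100, seed=5)
        assert p1 == p2
        assert p1 >= 1 / 101

    def test_n_sims_floor(self):
        with pytest.raises(ValueError, match="n_sims"):
            cline_significance(
                None, np.array([0, 1, 2]), np.array([0.2, 0.5, 0.8]),
                0.0, 1.0, n_sims=10,
            )

    def test_heterozygote_deficit_flagged(self):
        """A locus with zero heterozygotes among mid-range-h individuals is
        non-neutral with an 'Aa-' deviation."""
        rng = np.random.default_rng(8)
        n = 40
        h = rng.uniform(0.35, 0.65, n)
        g = 2 * rng.binomial(1, h)  # only homozygotes
        fit = fit_multinomial_cline(g, h, p_a=0.0, p_b=1.0)
        p, _ = cline_significance(fit, g, h, 0.0, 1.0, n_sims=300, seed=3)
        dev = deviation_summary(g, h, 0.0, 1.0, n_sims=300, seed=3)
        assert p < 0.05
        assert "Aa-" in dev
        assert "AA+" in dev and "aa+" in dev

    def test_all_heterozygote_locus_marks_excess(self):
        rng = np.random.default_rng(12)
        h = rng.uniform(0.3, 0.7, 40)
        g = np.ones(40, dtype=int)
        dev = deviation_summary(g, h, 0.0, 1.0, n_sims=300, seed=4)
        assert "Aa+" in dev and "AA-" in dev and "aa-" in dev

    def test_neutral_loci_mostly_unmarked(self):
        """Neutral simulations should earn no deviation marks ~95% of the
        time per locus (2.5% tails on three counts)."""
        rng = np.random.default_rng(21)
        h = rng.uniform(0, 1, 50)
        clean = 0
        n_loci = 30
        for i in range(n_loci):
            r = np.random.default_rng(1000 + i)
            g = r.binomial(2, h)
            dev = deviation_summary(g, h, 0.0, 1.0, n_sims=200, seed=i)
            if dev == "AA Aa aa":
                clean += 1
        assert clean >= 0.8 * n_loci


class TestPowerAgainstDistortion:
    def test_transmission_distorted_loci_flagged_far_above_neutral_rate(self):
        """Loci with transmission bias b = 0.4 show genotype-frequency
        departures the cline test detects at >= 5x the nominal rate."""
        from hybridzone.ancestry import polarize, estimate_ancestry
        from hybridzone.clines import cline_analysis
        from hybridzone.filtering import (
            allele_freq_differential, estimate_parental_freqs,
            select_differentiated,
        )
        from hybridzone.simulate import SimConfig, simulate_dataset

        n_distorted = 10
        config = SimConfig(
            seed=19, n_loci=40, frac_fixed=1.0, frac_high=0.0,
            n_parental_a=25, n_parental_b=25,
            class_counts={"F2": 30, "MULTIGEN_3": 20},
            missing_rate=0.0,
            distorted_loci=[(j, 0.4) for j in range(n_distorted)],
        )
        data = simulate_dataset(config)
        freqs = estimate_parental_freqs(data.matrix)
        diff = allele_freq_differential(freqs)
        ids = select_differentiated(diff, 1.0)
        pol, pf = polarize(data.matrix, freqs, ids)
        # genome-wide h from the undistorted loci (a genome-scale panel
        # would swamp the handful of distorted loci; 40 loci would not)
        neutral_ids = [lid for lid in ids if lid not in
                       {f"L{j + 1:05d}" for j in range(n_distorted)}]
        pol_h = pol.subset_loci_by_id(neutral_ids)
        anc = estimate_ancestry(pol_h, pf.loc[neutral_ids])
        from hybridzone.datamodel import Group

        admixed = pol.group_mask(Group.ADMIXED_CANDIDATE)
        h = anc.set_index("sample_id")["h"].loc[
            [s.sample_id for s, m in zip(pol.samples, admixed) if m]
        ].to_numpy()
        table = cline_analysis(
            pol, pf, h, diff=diff, n_sims=200, seed=7, sample_mask=admixed
        )
        distorted_ids = {f"L{j + 1:05d}" for j in range(n_distorted)}
        is_distorted = table["locus_id"].isin(distorted_ids)
        rate_distorted = (table.loc[is_distorted, "p_raw"] < 0.05).mean()
        rate_neutral = (table.loc[~is_distorted, "p_raw"] < 0.05).mean()
        assert rate_distorted >= 5 * max(rate_neutral, 0.05)


class TestFdr:
    @pytest.mark.parametrize(
        "k,expected",
        [(1, 0.05), (23, 0.013), (50, 0.011), (152, 0.009)],
    )
    def test_by_alpha_values(self, k, expected):
        assert round(by_alpha(k), 3) == expected

    def test_by_alpha_rejects_bad_k(self):
        with pytest.raises(ValueError):
            by_alpha(0)

    def test_bh_closed_form_and_single(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_nan_propagates(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    @staticmethod
    def naive_bh(p):
        """O(k^2) reference: step-up definition with cumulative minima."""
        p = np.asarray(p, float)
        k = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(k)
        running_min = 1.0
        for rank_from_end in range(k, 0, -1):
            i = order[rank_from_end - 1]
            running_min = min(running_min, p[i] * k / rank_from_end)
            adj[i] = running_min
        return adj

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bh_matches_naive_reference(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), self.naive_bh(pvals), atol=1e-12
        )

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1), min_size=2, max_size=20
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bh_monotone_and_permutation_equivariant(self, pvals, rnd):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
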