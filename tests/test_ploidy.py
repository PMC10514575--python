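"""Ploidy likelihoods, priors, vector MLE, multiploidy LRT and bootstrap."""

import io
import itertools

import numpy as np
import pytest
from scipy.stats import binom

from pilepop.likelihood import genotype_loglik
from pilepop.pileup import parse_mpileup
from pilepop.ploidy import (PloidyConfig, _site_contribution, bootstrap_ploidy,
                            collect_site_data, expected_freq_K, genotype_prior,
                            infer_ploidy, multiploidy_lrt, per_site_logliks,
                            ploidy_vector_mle, prob_major_ancestral)

from pilepop.simulate import SimConfig, simulate_text

from helpers import make_reads


class TestGenotypePrior:
    def test_hwe_diploid_half(self):
        assert genotype_prior(2, 0.5) == pytest.approx([0.25, 0.5, 0.25])

    def test_fixed_ancestral(self):
        assert genotype_prior(3, 0.0) == pytest.approx([1, 0, 0, 0])

    def test_tetraploid_binomial(self):
        assert genotype_prior(4, 0.5) == pytest.approx(
            [0.0625, 0.25, 0.375, 0.25, 0.0625])

    def test_uniform_mode(self):
        assert genotype_prior(3, 0.9, mode="uniform") == pytest.approx(
            [0.25] * 4)


class TestSpectrumSummaries:
    def test_expected_freq_small_n(self):
        # N=4, K=1: (1*6/11 + 2*3/11 + 3*2/11)/4 = (18/11)/4
        assert expected_freq_K(1.0, 2) == pytest.approx(18 / 44)

    def test_expected_freq_uniform_limit(self):
        assert expected_freq_K(1e-9, 50) == pytest.approx(0.5, abs=1e-6)

    def test_expected_freq_decreasing_in_k(self):
        vals = [expected_freq_K(k, 100) for k in (0.5, 1.0, 2.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_prob_major_ancestral_small_n(self):
        # N=4, K=1: p(1)+p(2) = (6+3)/11
        assert prob_major_ancestral(1.0, 2) == pytest.approx(9 / 11)

    @pytest.mark.parametrize("k", [0.2, 1.0, 3.0])
    def test_prob_major_ancestral_bounds(self, k):
        assert 0.5 <= prob_major_ancestral(k, 100) <= 1.0


class TestSiteContribution:
    def test_uniform_prior_is_log_mean(self):
        gl = genotype_loglik(make_reads("AAC"), 0, 1, 2).loglik
        val = _site_contribution(gl, 2, 0.3, 0.7, 1.0, uniform=True)
        assert val == pytest.approx(np.log(np.mean(np.exp(gl))))

    def test_known_ancestral_reduces_to_plain_mixture(self):
        """P(R=major)=1 collapses the ancestral mixture to the binomial-
        weighted genotype sum (the simple known-polarisation form)."""
        rng = np.random.default_rng(19)
        for _ in range(20):
            y = int(rng.integers(1, 6))
            gl = rng.normal(size=y + 1) * 3
            f = float(rng.random())
            direct = np.log(np.sum(np.exp(gl) * binom.pmf(np.arange(y + 1),
                                                          y, f)))
            val = _site_contribution(gl, y, f, 1.0 - f, 1.0, uniform=False)
            assert val == pytest.approx(direct, rel=1e-10)

    def test_fifty_fifty_ancestral_mixture(self):
        """Unknown polarisation with a spectrum prior: both polarisations
        condition on the same derived frequency, the genotype-likelihood
        vector being reversed for ancestral = minor."""
        rng = np.random.default_rng(23)
        y = 3
        gl = rng.normal(size=4)
        f = 0.2
        t1 = np.sum(np.exp(gl) * binom.pmf(np.arange(4), 3, f))
        t2 = np.sum(np.exp(gl[::-1]) * binom.pmf(np.arange(4), 3, f))
        expected = np.log(0.5 * t1 + 0.5 * t2)
        assert _site_contribution(gl, y, f, f, 0.5, False) == pytest.approx(
            expected, rel=1e-10)

    def test_complementary_frequencies_collapse_polarisation(self):
        """With per-site complementary frequencies (f, 1-f) the two
        polarisation terms coincide, so P(R=major) has no effect — the
        algebraic reason the per-site mode fixes P(R=major) = 1."""
        rng = np.random.default_rng(27)
        gl = rng.normal(size=5)
        for p in (0.3, 0.7, 1.0):
            assert _site_contribution(gl, 4, 0.2, 0.8, p, False) == \
                pytest.approx(_site_contribution(gl, 4, 0.2, 0.8, 1.0, False))

    def test_spectrum_prior_distinguishes_polarisation_weight(self):
        rng = np.random.default_rng(28)
        gl = rng.normal(size=4) * 2
        vals = {p: _site_contribution(gl, 3, 0.1, 0.1, p, False)
                for p in (0.5, 0.9)}
        assert vals[0.5] != pytest.approx(vals[0.9])


class TestVectorMLEAndLRTs:
    def test_equal_logliks_zero_lrt(self):
        mat = np.array([[1.0, 1.0]])
        mle, lrt = ploidy_vector_mle(mat, (2, 3))
        assert lrt == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(29)
        ploidies = (2, 3)
        for m in (1, 2, 3):
            mat = rng.normal(size=(m, 2)) * 5
            mle, lrt = ploidy_vector_mle(mat, ploidies)
            # brute force over all ploidy vectors
            totals = {}
            for combo in itertools.product(range(2), repeat=m):
                totals[combo] = sum(mat[i, c] for i, c in enumerate(combo))
            ranked = sorted(totals.values(), reverse=True)
            assert 2.0 * (ranked[0] - ranked[1]) == pytest.approx(lrt)
            best = max(totals, key=totals.get)
            assert tuple(np.asarray(ploidies)[list(best)]) == tuple(mle)

    def test_multiploidy_identical_rows_zero(self):
        mat = np.tile(np.array([[0.0, -3.0, -9.0]]), (4, 1))
        assert multiploidy_lrt(mat) == 0.0

    def test_multiploidy_matches_bruteforce(self):
        rng = np.random.default_rng(31)
        for m in (2, 3):
            mat = rng.normal(size=(m, 4)) * 4
            ll_free = sum(max(row) for row in mat)
            ll_equal = max(sum(mat[:, j]) for j in range(4))
            assert multiploidy_lrt(mat) == pytest.approx(
                max(0.0, 2.0 * (ll_free - ll_equal)))

    def test_multiploidy_single_sample_rejected(self):
        with pytest.raises(ValueError):
            multiploidy_lrt(np.zeros((1, 3)))


class TestEndToEnd:
    @staticmethod
    def _cohort(copy_spec, n_sites, seed):
        cfg = SimConfig(copy_spec=copy_spec, n_sites=n_sites, depth=10,
                        qual=20, pooled=False, K=1.0, n_e=10000,
                        depth_is_haploid=True, seed=seed)
        text, _ = simulate_text(cfg)
        return parse_mpileup(io.StringIO(text))

    def test_triploid_recovery(self):
        # single sample: the per-site frequency prior is circular here, so
        # use the population (folded) prior
        sites = self._cohort([(3, 1)], 600, seed=41)
        config = PloidyConfig(ploidies=(1, 2, 3, 4, 5), prior="folded")
        result = infer_ploidy(sites, config)
        assert result.mle_vector[0] == 3
        assert result.sites_used[0] > 500

    def test_bootstrap_whole_chromosome_is_point_estimate(self):
        sites = self._cohort([(2, 1), (4, 1)], 200, seed=43)
        config = PloidyConfig(ploidies=(2, 3, 4), prior="sample")
        cache, m = collect_site_data(sites, config.ploidies)
        per_site = per_site_logliks(cache, m, config)
        matrix = per_site.sum(axis=0)
        mle, _ = ploidy_vector_mle(matrix, config.ploidies)
        freq = bootstrap_ploidy(per_site, config.ploidies,
                                block_size=len(cache), n_boot=1, seed=0)
        for i, y in enumerate(mle):
            assert freq[i, list(config.ploidies).index(y)] == 1.0

    def test_bootstrap_frequencies_sum_to_one(self):
        sites = self._cohort([(4, 1)], 400, seed=47)
        config = PloidyConfig(ploidies=(2, 3, 4, 5), prior="folded")
        result = infer_ploidy(sites, config, n_boot=50, block_size=20,
                              seed=1)
        assert result.bootstrap_freq.sum(axis=1) == pytest.approx([1.0])
        # tetraploid recovered in the vast majority of replicates
        assert result.bootstrap_freq[0, 2] >= 0.9

    def test_missing_sample_sites_tracked(self):
        text = ("c\t1\tA\t2\t..\tII\t0\t*\t*\n"
                "c\t2\tA\t2\t.C\tII\t1\t.\tI\n")
        sites = parse_mpileup(io.StringIO(text))
        config = PloidyConfig(ploidies=(1, 2), prior="uniform")
        result = infer_ploidy(sites, config)
        assert list(result.sites_used) == [2, 1]
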