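"""Pooled allele-frequency likelihoods, estimators and SNP calling."""

import io

import numpy as np
import pytest

from pilepop.likelihood import choose_alleles
from pilepop.pileup import parse_mpileup
from pilepop.poolfreq import (SAFVector, freq_loglik, pop_freq_mle, read_saf,
                              run_pool, saf_estimators, saf_loglik, snp_lrt)
from pilepop.simulate import SimConfig, simulate_cohort, simulate_text

from helpers import make_site, random_site


class TestFreqLoglik:
    def test_f_zero_collapses_to_monoallelic(self):
        site = make_site("AAAAAC")
        alleles = choose_alleles(site)
        eps = 0.01
        ll_mono = 5 * np.log(1 - eps) + np.log(eps / 3)
        assert freq_loglik(site, alleles, 0.0) == pytest.approx(ll_mono)

    def test_hand_product_at_half(self):
        site = make_site("AAAAACCCCC")
        alleles = choose_alleles(site)
        expected = 10 * np.log(0.5 * 0.99 + 0.5 * 0.01 / 3)
        assert freq_loglik(site, alleles, 0.5) == pytest.approx(expected)

    def test_concavity_on_grid(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0.0, 1.0, 101)
        for _ in range(10):
            site = random_site(rng)
            ll = freq_loglik(site, choose_alleles(site), grid)
            second_diff = np.diff(ll, 2)
            assert np.all(second_diff <= 1e-9)


class TestPopFreqMLE:
    def test_all_minor_reads(self):
        site = make_site("CCCC")
        alleles = choose_alleles(site)
        # C is the major allele of this site; the minor has frequency 0
        assert pop_freq_mle(site, alleles) == pytest.approx(0.0, abs=1e-5)

    def test_pure_two_allele_split(self):
        site = make_site("AACC")
        assert pop_freq_mle(site, choose_alleles(site)) == pytest.approx(
            0.5, abs=1e-4)

    def test_matches_dense_grid_argmax(self):
        site = make_site("AAAAAAAAAC")
        alleles = choose_alleles(site)
        grid = np.linspace(0.0, 1.0, 10001)
        brute = grid[np.argmax(freq_loglik(site, alleles, grid))]
        mle = pop_freq_mle(site, alleles)
        assert mle == pytest.approx(brute, abs=1e-4)
        # error-corrected proportion sits near the raw count 0.10
        assert 0.05 < mle < 0.15


class TestSAF:
    def test_no_reads_gives_flat_vector(self):
        site = make_site("")
        saf = saf_loglik(site, None, 2)
        assert np.all(saf.loglik == 0.0)

    def test_max_shifted_to_zero(self):
        site = make_site("AAAC")
        saf = saf_loglik(site, choose_alleles(site), 10)
        assert saf.loglik.max() == pytest.approx(0.0)

    def test_argmax_consistent_with_continuous_mle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            site = random_site(rng)
            alleles = choose_alleles(site)
            n = 20
            saf = saf_loglik(site, alleles, n)
            j_star = int(np.argmax(saf.loglik))
            f_cont = pop_freq_mle(site, alleles)
            # discrete argmax within one grid step of the rounded MLE
            assert abs(j_star - round(f_cont * n)) <= 1

    def test_single_minor_read_among_twenty(self):
        site = make_site("A" * 19 + "C")
        saf = saf_loglik(site, choose_alleles(site), 20)
        assert int(np.argmax(saf.loglik)) == 1

    def test_estimators_flat_and_point_mass(self):
        flat = SAFVector(2, np.zeros(3))
        f_mle, f_exp = saf_estimators(flat)
        assert f_mle == 0.0 and f_exp == pytest.approx(0.5)
        point = SAFVector(4, np.array([0.0, -60.0, -60.0, -60.0, -60.0]))
        assert saf_estimators(point) == pytest.approx((0.0, 0.0), abs=1e-10)

    def test_expected_value_bounds_and_weights(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            saf = SAFVector(8, rng.normal(size=9) - rng.normal(size=9).max())
            saf.loglik -= saf.loglik.max()
            _, f_exp = saf_estimators(saf)
            assert 0.0 <= f_exp <= 1.0
            assert saf.posterior().sum() == pytest.approx(1.0)


class TestSnpLRT:
    def test_monomorphic_perfect_reads(self):
        site = make_site("A" * 10, quals=40)
        assert snp_lrt(site, choose_alleles(site)) == pytest.approx(0.0,
                                                                    abs=1e-6)

    def test_matches_grid_oracle(self):
        site = make_site("AAAAAAAAAACCCCCCCCCC")
        alleles = choose_alleles(site)
        grid = np.linspace(0.0, 1.0, 10001)
        ll = freq_loglik(site, alleles, grid)
        brute = 2.0 * (ll.max() - ll[0])
        assert snp_lrt(site, alleles) == pytest.approx(brute, abs=1e-4)


class TestEstimatorBenchmarks:
    """Stochastic consistency of the three estimators on simulated pools."""

    @staticmethod
    def _estimates(n_samples, depth, seed, n_sites=1000, f=0.3):
        cfg = SimConfig(copy_spec=[(2, n_samples)], n_sites=n_sites,
                        depth=depth, qual=20, pooled=True, fixed_f=f,
                        seed=seed)
        text, truths = simulate_text(cfg)
        n = 2 * n_samples
        est_mle, est_exp, truth = [], [], []
        for site, tr in zip(parse_mpileup(io.StringIO(text)), truths):
            if site.total_depth == 0:
                continue
            alleles = choose_alleles(site)
            f_mle, f_exp = saf_estimators(saf_loglik(site, alleles, n))
            est_mle.append(f_mle)
            est_exp.append(f_exp)
            truth.append(tr.sample_freq)
        return map(np.array, (est_mle, est_exp, truth))

    def test_rmse_decreases_with_depth_and_sample_size(self):
        rmse = {}
        for m in (20, 50):
            for d in (1, 5):
                est, _, tru = self._estimates(m, d, seed=31)
                rmse[(m, d)] = np.sqrt(np.mean((est - tru) ** 2))
        assert rmse[(20, 5)] < rmse[(20, 1)]
        assert rmse[(50, 5)] < rmse[(50, 1)]
        assert rmse[(50, 1)] < rmse[(20, 1)]
        assert rmse[(50, 5)] < rmse[(20, 5)]

    def test_mle_less_biased_than_posterior_mean(self):
        est_mle, est_exp, tru = self._estimates(20, 5, seed=31,
                                                n_sites=1500)
        assert abs(np.mean(est_mle - tru)) < abs(np.mean(est_exp - tru))


class TestPipelineIO:
    def test_pool_output_roundtrip(self, tmp_path):
        cfg = SimConfig(copy_spec=[(2, 5)], n_sites=30, depth=8, qual=20,
                        pooled=True, fixed_f=0.3, seed=4)
        prefix = str(tmp_path / "sim")
        mpileup, _ = simulate_cohort(cfg, prefix)
        fout = str(tmp_path / "out.tsv.gz")
        fsaf = str(tmp_path / "saf.tsv.gz")
        n = run_pool(mpileup, fout, n_chrom=10, fsaf=fsaf)
        assert n > 0
        records = list(read_saf(fsaf))
        assert len(records) == n
        chrom, pos, saf = records[0]
        assert saf.n_chrom == 10 and saf.loglik.max() == pytest.approx(0.0,
                                                                       abs=1e-5)

    def test_snp_filter_reduces_output(self, tmp_path):
        cfg = SimConfig(copy_spec=[(2, 5)], n_sites=60, depth=8, qual=20,
                        pooled=True, fixed_f=0.05, seed=8)
        prefix = str(tmp_path / "sim")
        mpileup, _ = simulate_cohort(cfg, prefix)
        all_sites = run_pool(mpileup, str(tmp_path / "a.tsv.gz"))
        called = run_pool(mpileup, str(tmp_path / "b.tsv.gz"), lrt_snp=6.64)
        assert called < all_sites
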