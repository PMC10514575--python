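"""Reproducible benchmark experiments.

Each function simulates one of the package's reference study designs end to
end — generate an mpileup cohort, run the estimation pipeline, score the
result — and returns the summary statistic.  They are used both by the test
suite and by the reproduction script, and double as worked examples of how
the pieces compose.

All randomness derives from a single integer seed; sub-streams are spawned
deterministically so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import io

import numpy as np

from .assoc import assoc_lrt
from .benchmark import bench_assoc, bench_snp
from .likelihood import choose_alleles
from .pileup import parse_mpileup
from .ploidy import PloidyConfig, infer_ploidy
from .poolfreq import snp_lrt, saf_loglik
from .sfs import fit_K, observed_sfs_afl
from .simulate import SimConfig, simulate_text


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


def _pool_safs(fixed_f: float, n_samples: int, n_sites: int, depth: float,
               n_chrom: int, seed: int, qual: int = 20) -> list:
    cfg = SimConfig(copy_spec=[(2, n_samples)], n_sites=n_sites, depth=depth,
                    qual=qual, pooled=True, fixed_f=fixed_f, seed=seed)
    text, _ = simulate_text(cfg)
    out = []
    for site in parse_mpileup(io.StringIO(text)):
        if site.total_depth == 0:
            out.append(None)
            continue
        out.append(saf_loglik(site, choose_alleles(site), n_chrom))
    return out


def association_power(seed: int, n_each: int = 150, n_snps: int = 200,
                      depth: float = 20.0, f_causal: tuple = (0.09, 0.04),
                      f_null: float = 0.10,
                      alpha_fpr: float = 0.10) -> dict:
    """Power of the pooled case/control LRT at an empirical FPR.

    The reference design: 150 diploid cases and 150 diploid controls,
    causal sites at population frequencies 0.09 vs 0.04, null sites at
    0.10 in both groups, 200 SNPs per class, deep sequencing (mean 20x per
    sample) so genotype uncertainty is negligible.  The rejection threshold
    is the empirical (1 - alpha) quantile of the null-site LRTs.
    """
    n_chrom = 2 * n_each
    s = _subseeds(seed, 4)
    causal = [assoc_lrt(a, b).lrt for a, b in zip(
        _pool_safs(f_causal[0], n_each, n_snps, depth, n_chrom, s[0]),
        _pool_safs(f_causal[1], n_each, n_snps, depth, n_chrom, s[1]))
        if a and b]
    null = [assoc_lrt(a, b).lrt for a, b in zip(
        _pool_safs(f_null, n_each, n_snps, depth, n_chrom, s[2]),
        _pool_safs(f_null, n_each, n_snps, depth, n_chrom, s[3]))
        if a and b]
    power, threshold = bench_assoc(causal, null, alpha_fpr)
    return {"power": power, "threshold": threshold,
            "n_causal": len(causal), "n_null": len(null)}


def snp_calling_f1(seed: int, n_samples: int = 20, f_snp: float = 0.05,
                   depth: float = 2.0, n_sites: int = 5000,
                   lrt_threshold: float = 6.64) -> dict:
    """F1 of LRT-based SNP calling on a half-SNP, half-monomorphic panel."""
    s = _subseeds(seed, 2)
    lrts, truth = [], []
    for f, sub in ((f_snp, s[0]), (0.0, s[1])):
        cfg = SimConfig(copy_spec=[(2, n_samples)], n_sites=n_sites,
                        depth=depth, qual=20, pooled=True, fixed_f=f,
                        seed=sub)
        text, _ = simulate_text(cfg)
        for site in parse_mpileup(io.StringIO(text)):
            if site.total_depth == 0:
                lrts.append(0.0)
            else:
                lrts.append(snp_lrt(site, choose_alleles(site)))
            truth.append(f > 0.0)
    calls = [l >= lrt_threshold for l in lrts]
    return {"f1": bench_snp(calls, truth), "n_sites": len(calls)}


def k_recovery(seed: int, n_samples: int = 100, depth: float = 5.0,
               n_sites: int = 20000, k_true: float = 1.0,
               n_e: int = 10000) -> dict:
    """Fit the 1/f^K exponent to a likelihood-integrated (Fit_afl) spectrum.

    Sites are simulated with population frequencies from the neutral
    K = k_true spectrum on 2*n_e chromosomes.  Because the sample allele
    frequencies refer to the data-chosen minor allele, the observed
    spectrum is folded and the folded expected spectrum is fitted.
    """
    n_chrom = 2 * n_samples
    cfg = SimConfig(copy_spec=[(2, n_samples)], n_sites=n_sites, depth=depth,
                    qual=20, pooled=True, K=k_true, n_e=n_e, seed=seed)
    text, _ = simulate_text(cfg)
    safs = [saf_loglik(s, choose_alleles(s), n_chrom)
            for s in parse_mpileup(io.StringIO(text)) if s.total_depth > 0]
    observed = observed_sfs_afl(safs, folded=True)
    k_hat, kl = fit_K(observed, n_chrom, folded=True)
    return {"k_hat": k_hat, "kl": kl, "n_sites_used": len(safs)}


MIXED_PLOIDY_COHORT = [(2, 1), (3, 8), (4, 1)]


def ploidy_recovery(seed: int, copy_spec=None, n_sites: int = 1000,
                    haploid_depth: float = 10.0,
                    priors: tuple = ("sample", "folded", "ancestral"),
                    ploidies: tuple = (1, 2, 3, 4, 5)) -> dict:
    """Infer the ploidy vector of a mixed-ploidy cohort under several priors.

    The reference cohort is one diploid, eight triploids and one tetraploid
    sequenced at mean 10x per haploid genome copy over 1000 sites.
    """
    copy_spec = copy_spec or MIXED_PLOIDY_COHORT
    cfg = SimConfig(copy_spec=copy_spec, n_sites=n_sites, depth=haploid_depth,
                    qual=20, pooled=False, K=1.0, n_e=10000,
                    depth_is_haploid=True, seed=seed)
    text, _ = simulate_text(cfg)
    truth = [y for y, c in copy_spec for _ in range(c)]
    out = {"truth": truth, "priors": {}}
    for prior in priors:
        config = PloidyConfig(ploidies=ploidies, prior=prior)
        result = infer_ploidy(parse_mpileup(io.StringIO(text)), config)
        out["priors"][prior] = {
            "mle_vector": [int(y) for y in result.mle_vector],
            "correct": [int(y) for y in result.mle_vector] == truth,
            "lrt_ploidy": result.lrt_ploidy,
            "lrt_multiploidy": result.lrt_multiploidy,
        }
    return out
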