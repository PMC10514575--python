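"""Allele-frequency estimation and SNP calling from pooled sequencing.

A pool of ``M`` samples of ploidy ``Y`` contributes ``N = M * Y``
chromosomes per site but no per-individual read assignment.  Treating each
read as an independent draw from the pool, the log-likelihood of a minor
(derived) allele frequency ``f`` is

    ll(f) = sum over reads of log[ f * P(b|minor) + (1 - f) * P(b|major) ]

which is concave in ``f``.  Three estimators are reported per site:

* ``f_mle_pop`` — the continuous maximiser of ``ll`` on [0, 1]
  (population-frequency MLE, no sample-size assumption);
* ``f_mle_sample`` — the maximiser over the discrete sample frequencies
  ``j / N``;
* ``f_expected`` — the posterior mean of ``j / N`` under a uniform prior.

SNP calling is a 1-df likelihood-ratio test of ``f = 0`` against the MLE;
the conventional threshold 6.64 corresponds to p = 0.01.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import softmax

from .likelihood import allele_lik_table, choose_alleles, collapse_reads
from .pileup import BASES, FilterConfig, PileupSite, read_sites
from .likelihood import SiteAlleles

#: SNP-calling LRT threshold equivalent to p = 0.01 at 1 df
LRT_P01 = 6.64


@dataclass
class FreqEstimate:
    """Per-site allele-frequency estimates and polymorphism statistics."""

    f_mle_pop: float
    f_mle_sample: float | None
    f_expected: float | None
    lrt_snp: float


@dataclass
class SAFVector:
    """Max-shifted log-likelihoods over sample derived-allele counts 0..N."""

    n_chrom: int
    loglik: np.ndarray

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        if len(self.loglik) != self.n_chrom + 1:
            raise ValueError("SAF vector length must be n_chrom + 1")

    def posterior(self) -> np.ndarray:
        """Normalized posterior over counts under a uniform prior."""
        return softmax(self.loglik)


def _site_liks(site: PileupSite, alleles: SiteAlleles):
    """Collapsed per-read-class (P(b|minor), P(b|major), multiplicity)."""
    bases, quals, counts = collapse_reads(site.pooled())
    table = allele_lik_table(bases, quals)
    return table[:, alleles.minor], table[:, alleles.major], counts


def freq_loglik(site: PileupSite, alleles: SiteAlleles, f) -> float | np.ndarray:
    """Log-likelihood of minor-allele frequency ``f`` (scalar or array)."""
    lmin, lmaj, counts = _site_liks(site, alleles)
    f = np.asarray(f, dtype=float)
    mix = f[..., None] * lmin + (1.0 - f[..., None]) * lmaj
    out = np.log(mix) @ counts
    return float(out) if out.ndim == 0 else out


def pop_freq_mle(site: PileupSite, alleles: SiteAlleles,
                 tol: float = 1e-6) -> float:
    """Continuous MLE of the minor-allele frequency on [0, 1].

    Golden-section search with parabolic refinement (Brent, bounded); the
    boundaries are checked explicitly since the optimum of a concave
    likelihood often sits at 0 for monomorphic sites.
    """
    lmin, lmaj, counts = _site_liks(site, alleles)

    def neg_ll(f: float) -> float:
        return -float(np.log(f * lmin + (1.0 - f) * lmaj) @ counts)

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    cands = [(neg_ll(0.0), 0.0), (res.fun, float(res.x)), (neg_ll(1.0), 1.0)]
    return min(cands)[1]


def snp_lrt(site: PileupSite, alleles: SiteAlleles,
            f_mle: float | None = None) -> float:
    """1-df LRT of polymorphism: H0 f = 0 vs H1 f = MLE, floored at 0."""
    if f_mle is None:
        f_mle = pop_freq_mle(site, alleles)
    ll = freq_loglik(site, alleles, np.array([f_mle, 0.0]))
    return max(0.0, 2.0 * (ll[0] - ll[1]))


def saf_loglik(site: PileupSite, alleles: SiteAlleles, n_chrom: int) -> SAFVector:
    """Sample-allele-frequency log-likelihoods on the grid j / n_chrom.

    The vector is shifted so its maximum is 0; shifting (rather than
    normalising) preserves likelihood-ratio semantics between sites.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    grid = np.arange(n_chrom + 1) / n_chrom
    if site.total_depth == 0:
        return SAFVector(n_chrom, np.zeros(n_chrom + 1))
    ll = freq_loglik(site, alleles, grid)
    return SAFVector(n_chrom, ll - ll.max())


def saf_estimators(saf: SAFVector) -> tuple[float, float]:
    """(MLE, posterior mean) of the sample frequency from a SAF vector."""
    n = saf.n_chrom
    f_mle = int(np.argmax(saf.loglik)) / n  # ties resolve to the smaller j
    weights = saf.posterior()
    f_expected = float(np.arange(n + 1) / n @ weights)
    return f_mle, f_expected


@dataclass
class PoolSiteResult:
    """One output row of the pooled-data analyzer."""

    chrom: str
    pos: int
    ref: str
    depth: int
    alleles: SiteAlleles
    freq: FreqEstimate
    saf: SAFVector | None = None


def analyze_pool(sites: Iterable[PileupSite], n_chrom: int | None = None,
                 lrt_snp: float | None = None, lrt_bia: float | None = None,
                 lrt_tria: float | None = None) -> Iterator[PoolSiteResult]:
    """Per-site pooled analysis: alleles, LRTs and frequency estimators.

    ``lrt_snp``/``lrt_bia`` drop sites below the threshold; ``lrt_tria``
    drops sites *above* it (triallelic sites violate the biallelic model).
    ``n_chrom`` enables the known-sample-size estimators and SAF output.
    """
    for site in sites:
        if site.total_depth == 0:
            continue
        alleles = choose_alleles(site)
        f_mle = pop_freq_mle(site, alleles)
        lrt = snp_lrt(site, alleles, f_mle)
        if lrt_snp is not None and lrt < lrt_snp:
            continue
        if lrt_bia is not None and alleles.lrt_bi < lrt_bia:
            continue
        if lrt_tria is not None and alleles.lrt_tri > lrt_tria:
            continue
        saf = f_samp = f_exp = None
        if n_chrom is not None:
            saf = saf_loglik(site, alleles, n_chrom)
            f_samp, f_exp = saf_estimators(saf)
        ref = BASES[site.ref] if site.ref >= 0 else "N"
        yield PoolSiteResult(site.chrom, site.pos, ref, site.total_depth,
                             alleles, FreqEstimate(f_mle, f_samp, f_exp, lrt),
                             saf)


POOL_HEADER = ("#chrom\tpos\tref\tdepth\tmajor\tminor\tlrtSNP\tlrtBi\tlrtTri"
               "\tmaf_mle_pop\tmaf_mle_sample\tmaf_expected")


def write_pool_output(results: Iterable[PoolSiteResult], fout: str,
                      fsaf: str | None = None) -> int:
    """Write analyzer rows (and optionally SAF vectors) as gzipped TSV."""
    n = 0
    saf_handle = gzip.open(fsaf, "wt") if fsaf else None
    with gzip.open(fout, "wt") as out:
        out.write(POOL_HEADER + "\n")
        if saf_handle:
            saf_handle.write("#chrom\tpos\tmajor\tminor\tloglikes_0_to_N\n")
        for r in results:
            fs = "NA" if r.freq.f_mle_sample is None else f"{r.freq.f_mle_sample:.6g}"
            fe = "NA" if r.freq.f_expected is None else f"{r.freq.f_expected:.6g}"
            out.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.depth}"
                f"\t{r.alleles.major_base}\t{r.alleles.minor_base}"
                f"\t{r.freq.lrt_snp:.6g}\t{r.alleles.lrt_bi:.6g}"
                f"\t{r.alleles.lrt_tri:.6g}\t{r.freq.f_mle_pop:.6g}"
                f"\t{fs}\t{fe}\n")
            if saf_handle and r.saf is not None:
                vals = "\t".join(f"{v:.6g}" for v in r.saf.loglik)
                saf_handle.write(
                    f"{r.chrom}\t{r.pos}\t{r.alleles.major_base}"
                    f"\t{r.alleles.minor_base}\t{vals}\n")
            n += 1
    if saf_handle:
        saf_handle.close()
    return n


def read_saf(path: str) -> Iterator[tuple[str, int, SAFVector]]:
    """Iterate (chrom, pos, SAFVector) records from a SAF TSV file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            ll = np.array([float(x) for x in fields[4:]])
            yield fields[0], int(fields[1]), SAFVector(len(ll) - 1, ll)


def run_pool(fin: str, fout: str, config: FilterConfig | None = None,
             n_chrom: int | None = None, fsaf: str | None = None,
             lrt_snp: float | None = None, lrt_bia: float | None = None,
             lrt_tria: float | None = None) -> int:
    """File-to-file pooled analysis; returns the number of sites written."""
    sites = read_sites(fin, config)
    results = analyze_pool(sites, n_chrom, lrt_snp, lrt_bia, lrt_tria)
    return write_pool_output(results, fout, fsaf)
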