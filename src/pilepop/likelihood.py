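"""Nucleotide and genotype likelihoods for arbitrary ploidy.

The error model treats each base quality ``q`` as the probability
``eps = 10**(-q/10)`` that the sequenced base is wrong, with the error
spread uniformly over the three other nucleotides: a read ``b`` supports
allele ``a`` with probability ``1 - eps`` if ``b == a`` and ``eps / 3``
otherwise.

For a sample of ploidy ``Y`` carrying ``g`` copies of the minor (derived)
allele and ``Y - g`` copies of the major allele, each read is an equal-weight
draw from the sample's chromosomes, so its likelihood is the mixture
``(g/Y) * P(b|minor) + (1 - g/Y) * P(b|major)``; the genotype log-likelihood
is the sum of the per-read log mixtures.  All accumulation is in natural-log
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pileup import BASES, PileupSite, SampleReads

#: fixed nucleotide order used to break likelihood ties: A < C < G < T
NUCLEOTIDE_ORDER = BASES


def phred_to_error(q) -> float | np.ndarray:
    """Phred quality to error probability, ``10**(-q/10)``."""
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("Phred qualities must be >= 0")
    out = np.power(10.0, -q / 10.0)
    return float(out) if out.ndim == 0 else out


def read_allele_lik(base: int | str, allele: int | str, q: int) -> float:
    """P(read base | true allele) under the uniform error spectrum."""
    if isinstance(base, str):
        base = BASES.index(base)
    if isinstance(allele, str):
        allele = BASES.index(allele)
    eps = phred_to_error(q)
    return 1.0 - eps if base == allele else eps / 3.0


def collapse_reads(reads: SampleReads) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique (base, quality) read classes with multiplicities.

    Collapsing identical reads turns per-read sums into weighted sums over
    at most ``4 * n_distinct_quals`` classes, which is what makes dense
    frequency grids affordable on deep pools.
    """
    key = reads.bases.astype(np.int64) * 100000 + reads.quals.astype(np.int64)
    _, idx, counts = np.unique(key, return_index=True, return_counts=True)
    return reads.bases[idx].astype(np.intp), reads.quals[idx], counts.astype(float)


def allele_lik_table(bases: np.ndarray, quals: np.ndarray) -> np.ndarray:
    """(n_reads, 4) matrix of P(read | allele) for the four nucleotides."""
    eps = phred_to_error(quals.astype(float))
    table = np.tile((eps / 3.0)[:, None], (1, 4))
    table[np.arange(len(bases)), bases] = 1.0 - eps
    return table


@dataclass
class GenotypeLikelihoods:
    """Log-likelihoods over the count of minor/derived alleles 0..ploidy."""

    ploidy: int
    loglik: np.ndarray
    major: int
    minor: int
    missing: bool = False


@dataclass
class SiteAlleles:
    """Top three alleles at a site, ranked by pooled haploid likelihood."""

    major: int
    minor: int
    third: int
    lrt_bi: float
    lrt_tri: float

    @property
    def major_base(self) -> str:
        return BASES[self.major]

    @property
    def minor_base(self) -> str:
        return BASES[self.minor]


def genotype_loglik(reads: SampleReads, major: int, minor: int,
                    ploidy: int) -> GenotypeLikelihoods:
    """Genotype log-likelihood vector for one sample at one site.

    ``loglik[g]`` is the log-probability of the reads given ``g`` copies of
    ``minor`` and ``ploidy - g`` copies of ``major``.  Empty reads yield an
    all-zero vector flagged as missing.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if reads.depth == 0:
        return GenotypeLikelihoods(ploidy, np.zeros(ploidy + 1), major, minor,
                                   missing=True)
    bases, quals, counts = collapse_reads(reads)
    table = allele_lik_table(bases, quals)
    lmaj, lmin = table[:, major], table[:, minor]
    w = np.arange(ploidy + 1) / ploidy  # minor-allele dosage per genotype
    mix = w[:, None] * lmin[None, :] + (1.0 - w)[:, None] * lmaj[None, :]
    ll = np.log(mix) @ counts
    return GenotypeLikelihoods(ploidy, ll, major, minor)


def haploid_logliks(reads: SampleReads) -> np.ndarray:
    """Log-likelihood of the pooled reads for each candidate allele (len 4)."""
    bases, quals, counts = collapse_reads(reads)
    table = allele_lik_table(bases, quals)
    return counts @ np.log(table)


def rank_alleles(reads: SampleReads) -> np.ndarray:
    """Alleles sorted by decreasing haploid likelihood, ties A < C < G < T."""
    ll = haploid_logliks(reads)
    # stable sort on negated values keeps the fixed nucleotide order for ties
    return np.argsort(-ll, kind="stable")


def multiallelic_lrts(reads: SampleReads, order: np.ndarray) -> tuple[float, float]:
    """LRT statistics for a site being bi- vs mono- and tri- vs bi-allelic.

    The k-allelic log-likelihood takes each read as an equal-weight mixture
    over the top k alleles.  Both statistics are floored at 0 (nested
    models) and are compared to a chi-square with 1 df.
    """
    bases, quals, counts = collapse_reads(reads)
    table = allele_lik_table(bases, quals)
    i, j, z = order[0], order[1], order[2]
    ll_mono = counts @ np.log(table[:, i])
    ll_bi = counts @ np.log(0.5 * table[:, i] + 0.5 * table[:, j])
    ll_tri = counts @ np.log((table[:, i] + table[:, j] + table[:, z]) / 3.0)
    return (max(0.0, 2.0 * (ll_bi - ll_mono)),
            max(0.0, 2.0 * (ll_tri - ll_bi)))


def choose_alleles(site: PileupSite) -> SiteAlleles:
    """Identify major/minor/third alleles from all reads pooled across samples.

    Alleles are ranked by the haploid (ploidy 1) log-likelihood of the
    pooled reads; the ranking restricts downstream models to biallelic
    variation.  For monomorphic sites the minor allele assignment is
    arbitrary but harmless.
    """
    pooled = site.pooled()
    if pooled.depth == 0:
        raise ValueError(f"no retained reads at {site.chrom}:{site.pos}")
    order = rank_alleles(pooled)
    lrt_bi, lrt_tri = multiallelic_lrts(pooled, order)
    return SiteAlleles(int(order[0]), int(order[1]), int(order[2]),
                       lrt_bi, lrt_tri)
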