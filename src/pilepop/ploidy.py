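"""Ploidy inference and the multiploidy test.

For each sample ``m`` and candidate ploidy ``y`` the marginal log-likelihood
accumulates, over sites, the genotype likelihoods weighted by genotype
probabilities:

    ll(m, y) = sum_n log sum_a P(R=a) sum_i P(O_mn | G=i, y) * Binom(i; y, f_a)

where ``a`` ranges over the two pooled-data alleles (major/minor), ``R`` is
the ancestral state, ``i`` counts derived-allele copies and ``f_a`` is the
frequency of the derived (non-ancestral) allele under assignment ``a``.
Genotype probabilities are binomial in the allele frequency (HWE), or
uniform when no frequency information is trusted.

Four prior configurations are supported:

* ``uniform``   — flat genotype probabilities, no ancestral assignment;
* ``sample``    — f is the per-site pooled MLE, major allele ancestral
  (P(R=major) = 1);
* ``ancestral`` — f is E[F|K], the mean of the 1/f^K population spectrum,
  and P(R=major) is the spectrum's CDF at N/2 (the chance that the major
  allele is ancestral in a large sample);
* ``folded``    — f is E[F|K] with P(R=a) = 0.5, i.e. unknown polarisation.

The per-sample MLEs form the inferred ploidy vector; confidence comes from
an LRT against the second most likely vector, a multiploidy LRT against the
best equal-ploidy vector (chi-square, M-1 df), and a block bootstrap over
sites that addresses the composite-likelihood nature of the sum (sites are
linked, samples share history).

Sites where a sample has no retained reads are skipped for that sample
(tracked in ``sites_used``).  Ploidy 1 is not assessable on SNP-called
data: conditional on a site being called variable, the haploid model is
misspecified, so callers applying a SNP filter should start the tested
range at 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from scipy.stats import binom

from .likelihood import choose_alleles, genotype_loglik
from .pileup import PileupSite
from .poolfreq import pop_freq_mle
from .sfs import expected_sfs

PRIOR_MODES = ("uniform", "sample", "ancestral", "folded")


@dataclass
class PloidyConfig:
    """Prior configuration for ploidy likelihoods.

    ``n_e`` is the effective population size; the population spectrum uses
    N = 2 * n_e chromosomes (diploid-population convention).
    ``p_ancestral_major`` may be a probability or "auto" (computed from the
    K spectrum); it is only consulted in ``ancestral`` mode.
    """

    ploidies: Sequence[int] = tuple(range(1, 9))
    prior: str = "sample"
    K: float = 1.0
    n_e: int = 10000
    p_ancestral_major: float | str = "auto"

    def __post_init__(self) -> None:
        if self.prior not in PRIOR_MODES:
            raise ValueError(f"prior must be one of {PRIOR_MODES}")
        if min(self.ploidies) < 1:
            raise ValueError("ploidies must be >= 1")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if not (self.p_ancestral_major == "auto"
                or 0.0 <= float(self.p_ancestral_major) <= 1.0):
            raise ValueError("p_ancestral_major must be in [0,1] or 'auto'")


@dataclass
class PloidyResult:
    ploidies: tuple[int, ...]
    loglik_matrix: np.ndarray        # (M, n_ploidies)
    mle_vector: np.ndarray           # ploidy per sample
    lrt_ploidy: float
    lrt_multiploidy: float | None
    sites_used: np.ndarray           # per-sample count
    bootstrap_freq: np.ndarray | None = None  # (M, n_ploidies) frequencies


def genotype_prior(y: int, f: float, mode: str = "hwe") -> np.ndarray:
    """P(G = i | ploidy y, derived frequency f) for i = 0..y."""
    if mode == "uniform":
        return np.full(y + 1, 1.0 / (y + 1))
    return binom.pmf(np.arange(y + 1), y, f)


def expected_freq_K(K: float, n_e: int) -> float:
    """Mean derived-allele frequency of the 1/f^K population spectrum."""
    n = 2 * n_e
    p = expected_sfs(K, n)
    return float(np.arange(1, n) / n @ p)


def prob_major_ancestral(K: float, n_e: int) -> float:
    """P(major allele is ancestral): CDF of the 1/f^K spectrum at N/2."""
    n = 2 * n_e
    p = expected_sfs(K, n)
    f = np.arange(1, n)
    return float(p[f <= n / 2].sum())


@dataclass
class _SiteCache:
    """Per-site quantities reusable across prior configurations."""

    f_mle: float                     # pooled minor-allele frequency MLE
    gl: list[dict[int, np.ndarray] | None] = field(default_factory=list)
    # gl[m][y] = genotype log-likelihood vector (len y+1, minor = derived);
    # None when sample m has no reads at this site


def collect_site_data(sites: Iterable[PileupSite],
                      ploidies: Sequence[int]) -> tuple[list[_SiteCache], int]:
    """Genotype likelihoods and pooled frequency MLEs for every site.

    Returns the cache list and the number of samples.  Sites with no
    retained reads in any sample are dropped.
    """
    cache: list[_SiteCache] = []
    n_samples = None
    for site in sites:
        if n_samples is None:
            n_samples = len(site.samples)
        if site.total_depth == 0:
            continue
        alleles = choose_alleles(site)
        entry = _SiteCache(f_mle=pop_freq_mle(site, alleles))
        for reads in site.samples:
            if reads.depth == 0:
                entry.gl.append(None)
                continue
            entry.gl.append({
                y: genotype_loglik(reads, alleles.major, alleles.minor, y).loglik
                for y in ploidies})
        cache.append(entry)
    if n_samples is None:
        raise ValueError("no sites provided")
    return cache, n_samples


def _site_contribution(gl: np.ndarray, y: int, f_anc_major: float,
                       f_anc_minor: float, p_major_anc: float,
                       uniform: bool) -> float:
    """log P(O | y) at one site for one sample (stable log-sum-exp).

    ``f_anc_major``/``f_anc_minor`` are the derived-allele frequencies to
    condition the genotype prior on under the two polarisations.  With a
    per-site estimated frequency these are complementary (f, 1 - f), which
    makes the two terms coincide — hence the ``sample`` mode's
    P(R=major)=1 convention.  With a population-spectrum prior the derived
    frequency is E[F|K] whichever physical allele is derived, so both are
    E[F|K] and the polarisation mixture is informative.
    """
    m = gl.max()
    w = np.exp(gl - m)
    if uniform:
        return m + np.log(w.mean())
    # ancestral = major: gl is already indexed by derived (minor) copies
    t = p_major_anc * float(w @ genotype_prior(y, f_anc_major))
    if p_major_anc < 1.0:
        # ancestral = minor: the vector indexed by derived (major) copies
        # is the reversal of gl
        t += (1.0 - p_major_anc) * float(w[::-1] @ genotype_prior(y, f_anc_minor))
    if t <= 0.0:
        return -np.inf
    return m + np.log(t)


def per_site_logliks(cache: list[_SiteCache], n_samples: int,
                     config: PloidyConfig) -> np.ndarray:
    """(n_sites, M, n_ploidies) array of per-site log-likelihood terms.

    Missing sample/site combinations contribute 0 across all ploidies.
    """
    ploidies = list(config.ploidies)
    uniform = config.prior == "uniform"
    if config.prior == "sample":
        p_anc = 1.0
    elif config.prior == "folded":
        p_anc = 0.5
    elif config.p_ancestral_major == "auto":
        p_anc = prob_major_ancestral(config.K, config.n_e)
    else:
        p_anc = float(config.p_ancestral_major)
    f_const = None
    if config.prior in ("ancestral", "folded"):
        f_const = expected_freq_K(config.K, config.n_e)

    out = np.zeros((len(cache), n_samples, len(ploidies)))
    for s, entry in enumerate(cache):
        if f_const is None:
            f1, f2 = entry.f_mle, 1.0 - entry.f_mle
        else:
            f1 = f2 = f_const
        for m, gl_by_y in enumerate(entry.gl):
            if gl_by_y is None:
                continue
            for p, y in enumerate(ploidies):
                out[s, m, p] = _site_contribution(gl_by_y[y], y, f1, f2,
                                                  p_anc, uniform)
    return out


def ploidy_vector_mle(loglik_matrix: np.ndarray,
                      ploidies: Sequence[int]) -> tuple[np.ndarray, float]:
    """Per-sample MLE ploidies and the LRT against the runner-up vector.

    The second most likely vector differs from the best in exactly one
    sample, changed to its runner-up ploidy, so the LRT is twice the
    smallest per-sample margin.
    """
    mat = np.asarray(loglik_matrix, dtype=float)
    idx = mat.argmax(axis=1)
    mle = np.asarray(ploidies)[idx]
    if mat.shape[1] < 2:
        return mle, 0.0
    sorted_rows = np.sort(mat, axis=1)
    margins = sorted_rows[:, -1] - sorted_rows[:, -2]
    return mle, float(max(0.0, 2.0 * margins.min()))


def multiploidy_lrt(loglik_matrix: np.ndarray) -> float:
    """LRT of the per-sample MLE vector against the best equal-ploidy vector.

    Compared to a chi-square with M-1 degrees of freedom; requires M >= 2.
    """
    mat = np.asarray(loglik_matrix, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("multiploidy test requires at least 2 samples")
    ll_free = mat.max(axis=1).sum()
    ll_equal = mat.sum(axis=0).max()
    return float(max(0.0, 2.0 * (ll_free - ll_equal)))


def bootstrap_ploidy(per_site: np.ndarray, ploidies: Sequence[int],
                     block_size: int, n_boot: int,
                     seed: int | None = None) -> np.ndarray:
    """Block bootstrap of the MLE ploidy vector over sites.

    The chromosome is partitioned into contiguous blocks of ``block_size``
    sites; each replicate resamples blocks with replacement to the original
    block count.  Returns an (M, n_ploidies) matrix of per-sample inferred-
    ploidy frequencies across replicates.
    """
    if block_size < 1 or n_boot < 1:
        raise ValueError("block_size and n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites, n_samples, n_ploidy = per_site.shape
    starts = np.arange(0, n_sites, block_size)
    block_sums = np.add.reduceat(per_site, starts, axis=0)
    freq = np.zeros((n_samples, n_ploidy))
    for _ in range(n_boot):
        pick = rng.integers(0, len(starts), size=len(starts))
        mat = block_sums[pick].sum(axis=0)
        idx = mat.argmax(axis=1)
        freq[np.arange(n_samples), idx] += 1.0
    return freq / n_boot


def infer_ploidy(sites: Iterable[PileupSite], config: PloidyConfig,
                 n_boot: int = 0, block_size: int = 100,
                 seed: int | None = None) -> PloidyResult:
    """Full ploidy inference: likelihood matrix, MLE vector, LRTs, bootstrap."""
    cache, n_samples = collect_site_data(sites, config.ploidies)
    per_site = per_site_logliks(cache, n_samples, config)
    matrix = per_site.sum(axis=0)
    sites_used = np.array([
        sum(1 for entry in cache if entry.gl[m] is not None)
        for m in range(n_samples)])
    mle, lrt_p = ploidy_vector_mle(matrix, config.ploidies)
    lrt_multi = multiploidy_lrt(matrix) if n_samples >= 2 else None
    boot = None
    if n_boot > 0:
        boot = bootstrap_ploidy(per_site, config.ploidies, block_size,
                                n_boot, seed)
    return PloidyResult(tuple(config.ploidies), matrix, mle, lrt_p,
                        lrt_multi, sites_used, boot)
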