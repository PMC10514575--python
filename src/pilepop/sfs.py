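"""Site-frequency-spectrum estimation and the 1/f^K shape fit.

Under the standard coalescent with infinite-sites mutation, the probability
that a variable site has derived-allele frequency ``f`` out of ``N``
chromosomes is proportional to ``1/f`` for ``f = 1 .. N-1``.  Generalising
the exponent to ``1/f**K`` gives a one-parameter family in which ``K = 1``
corresponds to constant population size, ``K > 1`` to a shrinking population
(excess of common variants removed, rare variants enriched) and ``K < 1``
to growth.

The observed spectrum can be built either by counting per-site
sample-frequency point estimates (``count``) or by summing per-site
posterior distributions computed from sample-allele-frequency likelihoods
under a uniform prior (``afl``), which propagates the data uncertainty of
low-coverage pools.  ``K`` is estimated by minimising the Kullback-Leibler
divergence D(observed || expected) over the variable frequency classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import minimize_scalar

from .poolfreq import SAFVector

K_BOUNDS = (0.01, 10.0)


def expected_sfs(K: float, n_chrom: int, folded: bool = False) -> np.ndarray:
    """Normalized expected spectrum p(f) ∝ 1/f**K over f = 1 .. N-1.

    When ``folded``, classes f and N-f are merged onto the support
    1 .. floor(N/2) (a class at exactly N/2 is not doubled).
    """
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    f = np.arange(1, n_chrom)
    p = f ** (-float(K))
    p /= p.sum()
    if folded:
        return fold_spectrum(p, n_chrom)
    return p


def fold_spectrum(p: np.ndarray, n_chrom: int) -> np.ndarray:
    """Merge derived-frequency classes f and N-f of an unfolded spectrum."""
    half = n_chrom // 2
    folded = np.array([p[f - 1] + (p[n_chrom - f - 1] if f != n_chrom - f else 0.0)
                       for f in range(1, half + 1)])
    return folded


@dataclass
class SFSModel:
    """Observed spectrum over variable classes with a fitted 1/f^K shape."""

    n_chrom: int
    observed: np.ndarray
    K: float
    folded: bool
    kl: float

    @property
    def expected(self) -> np.ndarray:
        return expected_sfs(self.K, self.n_chrom, self.folded)


def observed_sfs_count(sample_freqs: Iterable[float], n_chrom: int,
                       folded: bool = False) -> np.ndarray:
    """Spectrum from per-site sample-frequency point estimates.

    Estimates are snapped to the grid j/N; the fixed classes j = 0 and
    j = N are excluded before normalisation.
    """
    j = np.rint(np.asarray(list(sample_freqs), dtype=float) * n_chrom).astype(int)
    hist = np.bincount(j[(j > 0) & (j < n_chrom)], minlength=n_chrom)[1:n_chrom]
    total = hist.sum()
    if total == 0:
        raise ValueError("all sites monomorphic: empty spectrum")
    p = hist / total
    return fold_spectrum(p, n_chrom) if folded else p


def observed_sfs_afl(saf_records: Iterable[SAFVector], threshold: float = 0.0,
                     folded: bool = False) -> np.ndarray:
    """Spectrum from summed per-site posteriors over sample frequencies.

    Each site's uniform-prior posterior is truncated at ``threshold``
    (entries below it zeroed, the rest renormalised per site) before
    summation; the default 0 keeps the full posterior.  Sites therefore
    contribute fractional counts to every frequency class they support.
    """
    total = None
    n_chrom = None
    for saf in saf_records:
        if n_chrom is None:
            n_chrom = saf.n_chrom
            total = np.zeros(n_chrom + 1)
        elif saf.n_chrom != n_chrom:
            raise ValueError("inconsistent n_chrom across SAF records")
        post = saf.posterior()
        if threshold > 0.0:
            post = np.where(post < threshold, 0.0, post)
            s = post.sum()
            if s == 0.0:
                continue
            post = post / s
        total += post
    if n_chrom is None:
        raise ValueError("no SAF records")
    variable = total[1:n_chrom]
    s = variable.sum()
    if s == 0.0:
        raise ValueError("all posterior mass on fixed classes: empty spectrum")
    p = variable / s
    return fold_spectrum(p, n_chrom) if folded else p


def kl_divergence(observed: np.ndarray, expected: np.ndarray) -> float:
    """D(observed || expected); zero observed classes contribute nothing."""
    mask = observed > 0
    return float(np.sum(observed[mask]
                        * np.log(observed[mask] / expected[mask])))


def fit_K(observed: np.ndarray, n_chrom: int,
          folded: bool = False) -> tuple[float, float]:
    """Fit the 1/f^K exponent by KL minimisation; returns (K_hat, kl).

    Golden-section/Brent search on K in [0.01, 10]; a degenerate observed
    spectrum (all mass in one class) pushes the fit to a boundary, which is
    reported with a warning.
    """
    observed = np.asarray(observed, dtype=float)
    if not np.isclose(observed.sum(), 1.0, atol=1e-6):
        raise ValueError("observed spectrum must sum to 1")

    def obj(K: float) -> float:
        return kl_divergence(observed, expected_sfs(K, n_chrom, folded))

    res = minimize_scalar(obj, bounds=K_BOUNDS, method="bounded",
                          options={"xatol": 1e-4})
    cands = [(obj(K_BOUNDS[0]), K_BOUNDS[0]), (res.fun, float(res.x)),
             (obj(K_BOUNDS[1]), K_BOUNDS[1])]
    kl, k_hat = min(cands)
    if np.count_nonzero(observed) == 1:
        warnings.warn("degenerate observed spectrum: K fit is at a boundary",
                      stacklevel=2)
    return k_hat, float(kl)


def fit_sfs(observed: np.ndarray, n_chrom: int, folded: bool = False) -> SFSModel:
    """Bundle an observed spectrum with its fitted K."""
    k_hat, kl = fit_K(observed, n_chrom, folded)
    return SFSModel(n_chrom, observed, k_hat, folded, kl)
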