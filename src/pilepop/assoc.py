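"""Case/control association testing from pooled sequencing data.

The test compares the population allele frequency of two pools (cases and
controls) without assigning per-site counts.  For a group with SAF
log-likelihoods ``L_j`` over derived-allele counts ``j = 0..N`` and a
candidate population proportion ``p``, the group log-likelihood marginalises
the unknown sample count binomially:

    ll_group(p) = log sum_j exp(L_j) * Binom(j; N, p)

The null (shared frequency) maximises ``ll_cases(p) + ll_controls(p)`` over
a single ``p``; the alternative maximises each group separately.  The LRT
``2 * (ll1 - ll0)`` is compared to a chi-square with 1 df.  Because the
groups may have different chromosome counts, the shared parameter is the
continuous proportion ``p``, scanned on a dense grid (step 1e-3).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, chi2

from .poolfreq import SAFVector

P_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class AssocResult:
    lrt: float
    p_shared: float
    p_cases: float
    p_controls: float

    @property
    def pvalue(self) -> float:
        return float(chi2.sf(self.lrt, df=1))


@lru_cache(maxsize=8)
def _binom_logpmf_grid(n_chrom: int) -> np.ndarray:
    """(N+1, len(P_GRID)) matrix of log Binom(j; N, p); cached per N."""
    j = np.arange(n_chrom + 1)[:, None]
    with np.errstate(divide="ignore"):
        return binom.logpmf(j, n_chrom, P_GRID[None, :])


def group_loglik_curve(saf: SAFVector) -> np.ndarray:
    """Group log-likelihood over the shared p grid."""
    mat = _binom_logpmf_grid(saf.n_chrom)
    return logsumexp(saf.loglik[:, None] + mat, axis=0)


def assoc_lrt(saf_cases: SAFVector, saf_controls: SAFVector) -> AssocResult:
    """1-df LRT of H0: f_cases = f_controls against unequal frequencies."""
    ll_a = group_loglik_curve(saf_cases)
    ll_b = group_loglik_curve(saf_controls)
    shared = ll_a + ll_b
    i0 = int(np.argmax(shared))
    ia, ib = int(np.argmax(ll_a)), int(np.argmax(ll_b))
    lrt = max(0.0, 2.0 * (ll_a[ia] + ll_b[ib] - shared[i0]))
    return AssocResult(lrt, float(P_GRID[i0]), float(P_GRID[ia]),
                       float(P_GRID[ib]))


def run_assoc(saf_cases: Iterable[tuple[str, int, SAFVector]],
              saf_controls: Iterable[tuple[str, int, SAFVector]],
              fout: str) -> int:
    """Per-site association test over two aligned SAF record streams."""
    n = 0
    with gzip.open(fout, "wt") as out:
        out.write("#chrom\tpos\tlrt\tpvalue\n")
        for (chrom_a, pos_a, saf_a), (chrom_b, pos_b, saf_b) in zip(
                saf_cases, saf_controls):
            if (chrom_a, pos_a) != (chrom_b, pos_b):
                raise ValueError(
                    f"unaligned SAF records: {chrom_a}:{pos_a} vs {chrom_b}:{pos_b}")
            res = assoc_lrt(saf_a, saf_b)
            out.write(f"{chrom_a}\t{pos_a}\t{res.lrt:.6g}\t{res.pvalue:.6g}\n")
            n += 1
    return n
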