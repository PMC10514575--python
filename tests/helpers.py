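"""Shared construction helpers for the test suite."""

import io

import numpy as np

from pilepop.pileup import BASES, PileupSite, SampleReads, parse_mpileup


def make_reads(bases: str, quals=20) -> SampleReads:
    codes = np.array([BASES.index(b) for b in bases], dtype=np.int8)
    if np.isscalar(quals):
        q = np.full(len(bases), quals, dtype=np.int16)
    else:
        q = np.asarray(quals, dtype=np.int16)
    return SampleReads(codes, q, np.zeros(len(bases), dtype=np.int8))


def make_site(bases: str, quals=20, chrom="chr1", pos=1, ref=0) -> PileupSite:
    return PileupSite(chrom, pos, ref, [make_reads(bases, quals)])


def parse_text(text: str, **kwargs) -> list[PileupSite]:
    return list(parse_mpileup(io.StringIO(text), **kwargs))


def random_site(rng: np.random.Generator, max_reads: int = 30) -> PileupSite:
    n = rng.integers(1, max_reads + 1)
    codes = rng.integers(0, 4, n).astype(np.int8)
    quals = rng.integers(10, 41, n).astype(np.int16)
    strands = rng.integers(0, 2, n).astype(np.int8)
    return PileupSite("chr1", 1, 0, [SampleReads(codes, quals, strands)])
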