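"""Synthetic mpileup generator with ground-truth tables.

The generator mirrors the sampling scheme used to benchmark the estimators:
per site, a population derived-allele frequency is drawn from the 1/f^K
spectrum on ``2 * n_e`` chromosomes (or held fixed), each sample's genotype
is binomial in that frequency, the number of mapped reads per sample is
Poisson, each read carries the derived allele with probability g/Y, and a
sequencing error (probability ``10**(-qual/10)``) substitutes one of the
three other nucleotides uniformly.  The ancestral allele is the mpileup
reference, so correct reads of ancestral chromosomes print as ``.``/``,``.

``depth`` is the Poisson mean per sample; with ``depth_is_haploid`` the
mean scales with ploidy (an "average depth at the haploid level"), which is
the natural parameterisation when comparing samples of different ploidy.
Pooled mode concatenates all samples into a single mpileup column, exactly
as pooled library sequencing would.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

from .pileup import BASES
from .sfs import expected_sfs

_PLUS_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)
_MINUS_CHARS = np.frombuffer(b"acgt", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study design for one simulated cohort.

    ``copy_spec`` lists (ploidy, count) pairs, e.g. ``[(2, 10)]`` for ten
    diploids.  Exactly one frequency mode is active: ``fixed_f`` pins the
    population derived-allele frequency, otherwise frequencies are drawn
    from the 1/f^K spectrum with ``K`` and effective size ``n_e``.
    """

    copy_spec: list[tuple[int, int]] = field(default_factory=lambda: [(2, 10)])
    n_sites: int = 1000
    depth: float = 20.0
    qual: int = 20
    pooled: bool = True
    K: float = 1.0
    n_e: int = 10000
    fixed_f: float | None = None
    depth_is_haploid: bool = False
    chrom: str = "sim1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if self.fixed_f is not None and not 0.0 <= self.fixed_f <= 1.0:
            raise ValueError("fixed_f must be in [0, 1]")

    @property
    def ploidies(self) -> np.ndarray:
        return np.concatenate([np.full(c, y, dtype=int)
                               for y, c in self.copy_spec])

    @property
    def n_samples(self) -> int:
        return sum(c for _, c in self.copy_spec)

    @property
    def n_chrom(self) -> int:
        return int(self.ploidies.sum())


@dataclass
class TruthRecord:
    """Ground truth for one simulated site."""

    pos: int
    pop_freq: float
    sample_freq: float      # total derived copies / total chromosomes
    genotypes: np.ndarray   # derived-allele copies per sample
    ancestral: int          # base code; also the mpileup reference
    derived: int


def parse_copy_spec(text: str) -> list[tuple[int, int]]:
    """Parse a ``PLOIDYxCOUNT[,...]`` string, e.g. ``"2x1,3x8,4x1"``."""
    out = []
    for chunk in text.split(","):
        y, c = chunk.lower().split("x")
        out.append((int(y), int(c)))
    return out


@lru_cache(maxsize=8)
def _freq_cdf(K: float, n: int) -> np.ndarray:
    return np.cumsum(expected_sfs(K, n))


def draw_site(config: SimConfig, rng: np.random.Generator,
              pos: int = 1) -> TruthRecord:
    """Draw one site's population frequency, alleles and genotypes."""
    if config.fixed_f is not None:
        f = config.fixed_f
    else:
        n = 2 * config.n_e
        cdf = _freq_cdf(config.K, n)
        f = (int(np.searchsorted(cdf, rng.random())) + 1) / n
    anc, der = rng.choice(4, size=2, replace=False)
    ploidies = config.ploidies
    genotypes = rng.binomial(ploidies, f)
    sample_freq = float(genotypes.sum()) / config.n_chrom
    return TruthRecord(pos, f, sample_freq, genotypes, int(anc), int(der))


def _sample_column(n_reads: int, g: int, y: int, truth: TruthRecord,
                   config: SimConfig, rng: np.random.Generator) -> tuple[str, str]:
    if n_reads == 0:
        return "*", "*"
    derived = rng.random(n_reads) < g / y
    true_base = np.where(derived, truth.derived, truth.ancestral)
    err = rng.random(n_reads) < 10.0 ** (-config.qual / 10.0)
    # a wrong call is uniform over the three other nucleotides
    base = np.where(err, (true_base + 1 + rng.integers(0, 3, n_reads)) % 4,
                    true_base)
    minus = rng.integers(0, 2, n_reads).astype(bool)
    chars = np.where(minus, _MINUS_CHARS[base], _PLUS_CHARS[base])
    is_ref = base == truth.ancestral
    chars = np.where(is_ref & ~minus, ord("."), chars)
    chars = np.where(is_ref & minus, ord(","), chars)
    bases = chars.astype(np.uint8).tobytes().decode("ascii")
    quals = chr(config.qual + 33) * n_reads
    return bases, quals


def emit_reads(truth: TruthRecord, config: SimConfig,
               rng: np.random.Generator) -> str:
    """Render one simulated site as an mpileup line."""
    ploidies = config.ploidies
    lam = config.depth * ploidies if config.depth_is_haploid \
        else np.full(len(ploidies), config.depth)
    n_reads = rng.poisson(lam)
    cols = [_sample_column(int(n), int(g), int(y), truth, config, rng)
            for n, g, y in zip(n_reads, truth.genotypes, ploidies)]
    ref = BASES[truth.ancestral]
    if config.pooled:
        bases = "".join(b for b, _ in cols if b != "*")
        quals = "".join(q for _, q in cols if q != "*")
        depth = len(bases)
        if depth == 0:
            bases = quals = "*"
        fields = [config.chrom, str(truth.pos), ref, str(depth), bases, quals]
    else:
        fields = [config.chrom, str(truth.pos), ref]
        for (b, q), n in zip(cols, n_reads):
            fields.extend([str(int(n)) if b != "*" else "0", b, q])
    return "\t".join(fields)


def simulate_sites(config: SimConfig) -> Iterator[tuple[str, TruthRecord]]:
    """Yield (mpileup line, truth record) pairs; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    for pos in range(1, config.n_sites + 1):
        truth = draw_site(config, rng, pos)
        yield emit_reads(truth, config, rng), truth


TRUTH_HEADER = "#pos\tpop_freq\tsample_freq\tancestral\tderived\tgenotypes"


def truth_row(truth: TruthRecord) -> str:
    genos = ",".join(str(int(g)) for g in truth.genotypes)
    return (f"{truth.pos}\t{truth.pop_freq:.8g}\t{truth.sample_freq:.8g}"
            f"\t{BASES[truth.ancestral]}\t{BASES[truth.derived]}\t{genos}")


def simulate_cohort(config: SimConfig, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.mpileup.gz`` and ``<prefix>.truth.tsv``; return paths."""
    mpileup_path = f"{out_prefix}.mpileup.gz"
    truth_path = f"{out_prefix}.truth.tsv"
    with gzip.open(mpileup_path, "wt") as mp, open(truth_path, "w") as tr:
        tr.write(TRUTH_HEADER + "\n")
        for line, truth in simulate_sites(config):
            mp.write(line + "\n")
            tr.write(truth_row(truth) + "\n")
    return mpileup_path, truth_path


def simulate_text(config: SimConfig) -> tuple[str, list[TruthRecord]]:
    """In-memory variant of :func:`simulate_cohort` for tests and pipelines."""
    lines, truths = [], []
    for line, truth in simulate_sites(config):
        lines.append(line)
        truths.append(truth)
    return "\n".join(lines) + "\n", truths
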