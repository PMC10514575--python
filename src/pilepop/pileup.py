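"""Reading and filtering samtools mpileup text.

The mpileup dialect handled here is the plain-text output of
``samtools mpileup`` (optionally gzipped): one line per genomic position with
TAB-separated ``chrom  pos  ref`` followed, for each sample, by a read depth,
an encoded read-base string and an ASCII-33 quality string.  An optional
fourth per-sample column (mapping qualities, ``-s`` dialect) is tolerated and
ignored.

Read-base strings are decoded into per-read base / quality / strand triplets:
``.``/``,`` become the reference base on the forward/reverse strand, letters
stand for themselves, ``^X`` (start-of-read plus mapping quality), ``$``
(end of read), ``*`` (deletion placeholder), ``>``/``<`` (reference skips)
and ``+n<seq>``/``-n<seq>`` indel runs carry no base call and are dropped.
Base-quality filtering happens at decode time, before any likelihood is
computed, so every downstream depth refers to reads that survived it.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterator

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}

# decode tables for the fast path (no escape characters present)
_CODE_TAB = np.full(256, -2, dtype=np.int8)  # -2 = invalid, -1 = ref
_STRAND_TAB = np.zeros(256, dtype=np.int8)
for _c, _i in BASE_CODE.items():
    _CODE_TAB[ord(_c)] = _i
    _CODE_TAB[ord(_c.lower())] = _i
    _STRAND_TAB[ord(_c.lower())] = 1
_CODE_TAB[ord(".")] = -1
_CODE_TAB[ord(",")] = -1
_STRAND_TAB[ord(",")] = 1

_ESCAPES = set("^$+-*><Nn")


class PileupParseError(ValueError):
    """Malformed mpileup line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class SampleReads:
    """Decoded reads of one sample at one site.

    ``bases`` holds integer base codes (0=A, 1=C, 2=G, 3=T), ``quals``
    Phred-scaled base qualities and ``strands`` 0 for forward / 1 for
    reverse.  The three arrays are always the same length.
    """

    bases: np.ndarray
    quals: np.ndarray
    strands: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.bases)

    def bases_str(self) -> str:
        return "".join(BASES[c] for c in self.bases)


@dataclass
class PileupSite:
    """One genomic position with per-sample decoded reads."""

    chrom: str
    pos: int
    ref: int  # base code, or -1 for N/unknown
    samples: list[SampleReads]

    @property
    def total_depth(self) -> int:
        return sum(s.depth for s in self.samples)

    def pooled(self) -> SampleReads:
        """All samples' reads concatenated, for pooled-data estimators."""
        if len(self.samples) == 1:
            return self.samples[0]
        return SampleReads(
            np.concatenate([s.bases for s in self.samples]),
            np.concatenate([s.quals for s in self.samples]),
            np.concatenate([s.strands for s in self.samples]),
        )


@dataclass
class FilterConfig:
    """Site- and read-level filters.

    All thresholds default to 0 (no filtering).  Depth thresholds apply to
    counts of reads that already passed the base-quality filter.
    """

    min_global_depth: int = 0
    max_global_depth: int | None = None
    min_sample_depth: int = 0
    min_base_qual: int = 0
    min_minor_count: int = 0
    min_minor_prop: float = 0.0

    def __post_init__(self) -> None:
        if min(self.min_global_depth, self.min_sample_depth,
               self.min_base_qual, self.min_minor_count) < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not 0.0 <= self.min_minor_prop <= 1.0:
            raise ValueError("min_minor_prop must be in [0, 1]")
        if (self.max_global_depth is not None
                and self.max_global_depth < self.min_global_depth):
            raise ValueError("max_global_depth < min_global_depth")


def _decode_fast(bases: str, quals: str, ref: int):
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    codes = _CODE_TAB[raw]
    strands = _STRAND_TAB[raw]
    codes = np.where(codes == -1, np.int8(ref), codes)
    q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    return codes.astype(np.int8), q, strands


def _decode_slow(bases: str, quals: str, ref: int, lineno: int):
    codes: list[int] = []
    strands: list[int] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret consumes the following mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise PileupParseError(lineno, "indel run without length")
            i += int(num)  # skip inserted/deleted sequence entirely
            continue
        if c in "*><":
            # deletion/skip placeholders consume a quality char but no base
            codes.append(-1)
            strands.append(0)
            i += 1
            continue
        if c in ".,":
            codes.append(ref)
            strands.append(0 if c == "." else 1)
        elif c.upper() in BASE_CODE:
            codes.append(BASE_CODE[c.upper()])
            strands.append(0 if c.isupper() else 1)
        elif c in "Nn":
            codes.append(-1)
            strands.append(0 if c == "N" else 1)
        else:
            raise PileupParseError(lineno, f"unexpected pileup character {c!r}")
        i += 1
    if len(codes) != len(quals):
        raise PileupParseError(
            lineno,
            f"decoded {len(codes)} bases but {len(quals)} quality characters")
    q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    return (np.asarray(codes, dtype=np.int8), q,
            np.asarray(strands, dtype=np.int8))


def decode_sample(bases: str, quals: str, ref: int, lineno: int = 0,
                  min_base_qual: int = 0) -> SampleReads:
    """Decode one sample's base/quality strings into a :class:`SampleReads`.

    Reads with quality below ``min_base_qual``, reads with no usable base
    call (``N``) and reads on an unknown reference consumed via ``.``/``,``
    are removed together with their quality and strand.
    """
    if bases in ("*", "") or quals == "*":
        e = np.empty(0)
        return SampleReads(e.astype(np.int8), e.astype(np.int16), e.astype(np.int8))
    if _ESCAPES.isdisjoint(bases):
        codes, q, strands = _decode_fast(bases, quals, ref)
        if len(codes) != len(q):
            raise PileupParseError(
                lineno, f"{len(codes)} bases but {len(q)} quality characters")
        if np.any(codes == -2):
            raise PileupParseError(lineno, "unexpected pileup character")
    else:
        codes, q, strands = _decode_slow(bases, quals, ref, lineno)
    keep = (codes >= 0) & (q >= min_base_qual)
    return SampleReads(codes[keep], q[keep], strands[keep])


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        head = source.read(2)
        if isinstance(head, str):
            rest = head + source.read()
            return io.StringIO(rest)
        data = head + source.read()
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        return io.StringIO(data.decode())
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_mpileup(source, config: FilterConfig | None = None,
                  on_error: str = "raise") -> Iterator[PileupSite]:
    """Iterate over the sites of an mpileup file or file-like object.

    Parameters
    ----------
    source : path or file-like
        Plain or gzipped mpileup text.
    config : FilterConfig, optional
        Only its ``min_base_qual`` is applied here (read-level filter);
        call :func:`passes_filters` for site-level filters.
    on_error : {"raise", "skip"}
        Whether a malformed line aborts parsing or is skipped.
    """
    config = config or FilterConfig()
    handle = _open_text(source)
    n_samples: int | None = None
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        try:
            site = _parse_line(line, lineno, config, n_samples)
        except PileupParseError:
            if on_error == "skip":
                continue
            raise
        if n_samples is None:
            n_samples = len(site.samples)
        yield site


def _parse_line(line: str, lineno: int, config: FilterConfig,
                n_samples: int | None) -> PileupSite:
    fields = line.split("\t")
    if len(fields) < 6:
        raise PileupParseError(lineno, f"{len(fields)} fields, expected >= 6")
    extra = len(fields) - 3
    if n_samples is not None:
        per = extra / n_samples
        if per not in (3.0, 4.0):
            raise PileupParseError(
                lineno, f"{len(fields)} fields for {n_samples} samples")
        step = int(per)
    elif extra % 3 == 0:
        step = 3
    elif extra % 4 == 0:
        step = 4  # mpileup -s dialect: trailing mapping-quality column
    else:
        raise PileupParseError(lineno, f"cannot split {extra} sample fields")
    chrom = fields[0]
    try:
        pos = int(fields[1])
    except ValueError:
        raise PileupParseError(lineno, f"non-integer position {fields[1]!r}")
    if pos < 1:
        raise PileupParseError(lineno, f"position {pos} < 1")
    ref = BASE_CODE.get(fields[2].upper(), -1)
    samples = []
    for off in range(3, len(fields), step):
        samples.append(decode_sample(fields[off + 1], fields[off + 2], ref,
                                     lineno, config.min_base_qual))
    return PileupSite(chrom, pos, ref, samples)


def minor_allele_stats(site: PileupSite) -> tuple[int, float]:
    """Count and proportion of the second most frequent base, pooled."""
    pooled = site.pooled()
    if pooled.depth == 0:
        return 0, 0.0
    counts = np.bincount(pooled.bases, minlength=4)
    minor_count = int(np.sort(counts)[-2])
    return minor_count, minor_count / pooled.depth


def passes_filters(site: PileupSite, config: FilterConfig) -> bool:
    """Site-level filters on depth and minor-allele support."""
    depth = site.total_depth
    if depth < config.min_global_depth:
        return False
    if config.max_global_depth is not None and depth > config.max_global_depth:
        return False
    if config.min_sample_depth > 0:
        if any(s.depth < config.min_sample_depth for s in site.samples):
            return False
    if config.min_minor_count > 0 or config.min_minor_prop > 0:
        count, prop = minor_allele_stats(site)
        if count < config.min_minor_count or prop < config.min_minor_prop:
            return False
    return True


def read_sites(source, config: FilterConfig | None = None,
               on_error: str = "raise") -> Iterator[PileupSite]:
    """Parse and yield only sites passing the site-level filters."""
    config = config or FilterConfig()
    for site in parse_mpileup(source, config, on_error):
        if passes_filters(site, config):
            yield site
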