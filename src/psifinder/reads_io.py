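"""Reading, trimming, filtering and collapsing of small RNA-seq reads.

Small RNA inserts are shorter than the sequencing read, so every read is
expected to run into the 3′ adapter; reads in which no adapter match is
found are discarded. After adapter removal an optional number of random
bases (NextFlex-style libraries) is stripped from each end of the
insert. Reads are then length- and quality-filtered and collapsed to
unique sequences with per-library counts; discard reasons are logged and
reconcile totals at every stage.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("psifinder.reads_io")

DEFAULT_PHRED_OFFSET = 33


@dataclass
class ReadRecord:
    """One FASTQ record; quality is the raw ASCII string (Phred+33)."""

    id: str
    sequence: str
    quality: str
    library: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id} has an empty sequence")
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def phred(self) -> list[int]:
        return [ord(c) - DEFAULT_PHRED_OFFSET for c in self.quality]


@dataclass
class CollapsedRead:
    """A unique insert sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class StageLog:
    """Bookkeeping for one processing stage; totals must reconcile."""

    stage: str
    n_in: int = 0
    n_out: int = 0
    discarded: Counter = field(default_factory=Counter)

    def check(self) -> None:
        if self.n_in != self.n_out + sum(self.discarded.values()):
            raise AssertionError(f"{self.stage}: read totals do not reconcile")


def read_fastq(path: str | Path, library: str = "") -> list[ReadRecord]:
    """Parse a FASTQ(.gz) file into ReadRecords."""
    path = Path(path)
    library = library or path.name.split(".")[0]
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            out.append(ReadRecord(header[1:].split()[0], seq, qual, library))
    return out


def _match_adapter(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> int:
    """Leftmost start of an adapter match (full, or a prefix of
    >= min_overlap bases reaching the read end); -1 if none. Up to
    ``max_mismatch`` substitutions are tolerated, no indels."""
    L, A = len(seq), len(adapter)
    for i in range(0, L - min_overlap + 1):
        span = min(A, L - i)
        mm = 0
        for a, b in zip(seq[i:i + span], adapter[:span]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return -1


def trim_adapter(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_overlap: int = 5,
    random_ends: int = 0,
    max_mismatch: int = 1,
) -> tuple[list[ReadRecord], StageLog]:
    """Remove the 3′ adapter and optional random end bases.

    The leftmost occurrence of the adapter (or an end-anchored prefix of
    at least ``min_overlap`` bases, with at most ``max_mismatch``
    substitutions) and everything 3′ of it is removed; ``random_ends``
    bases are then stripped from each end of the insert. Reads without
    an adapter match, or whose insert is consumed by the random ends,
    are discarded.
    """
    if not (5 <= min_overlap <= len(adapter)):
        raise ValueError("require adapter length >= min_overlap >= 5")
    log = StageLog("trim_adapter")
    kept: list[ReadRecord] = []
    for r in reads:
        log.n_in += 1
        i = _match_adapter(r.sequence, adapter, min_overlap, max_mismatch)
        if i < 0:
            log.discarded["no_adapter"] += 1
            continue
        if i <= 2 * random_ends:
            log.discarded["empty_insert"] += 1
            continue
        s, e = random_ends, i - random_ends
        kept.append(ReadRecord(r.id, r.sequence[s:e], r.quality[s:e], r.library))
        log.n_out += 1
    log.check()
    return kept, log


def filter_reads(
    reads: Iterable[ReadRecord],
    min_len: int,
    max_len: int,
    min_q: int | None = None,
    q_frac: float = 0.9,
) -> tuple[list[ReadRecord], StageLog]:
    """Length, N-content and (optional) quality filtering.

    A read is kept when ``min_len <= length <= max_len``, it contains no
    N, and — if ``min_q`` is given — at least ``q_frac`` of its bases
    have Phred quality >= ``min_q``.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    log = StageLog("filter_reads")
    kept: list[ReadRecord] = []
    for r in reads:
        log.n_in += 1
        L = len(r.sequence)
        if not (min_len <= L <= max_len):
            log.discarded["length"] += 1
            continue
        if "N" in r.sequence:
            log.discarded["contains_N"] += 1
            continue
        if min_q is not None:
            n_ok = sum(1 for q in r.phred() if q >= min_q)
            if n_ok < q_frac * L:
                log.discarded["quality"] += 1
                continue
        kept.append(r)
        log.n_out += 1
    log.check()
    return kept, log


def collapse_reads(reads: Iterable[ReadRecord]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with per-library counts.

    Output is sorted lexicographically by sequence; total counts are
    conserved (sum of all counts equals the number of input reads).
    """
    table: dict[str, Counter] = {}
    for r in reads:
        table.setdefault(r.sequence, Counter())[r.library] += 1
    return [CollapsedRead(seq, dict(sorted(table[seq].items())))
            for seq in sorted(table)]


@dataclass
class MaskedGroup:
    """Unique (sequence, low-quality position set) group of one library.

    Used by the Mn²⁺ mutational branch, where per-base qualities decide
    which base calls may count as Ψ evidence.
    """

    sequence: str
    lowq: tuple[int, ...]
    count: int


def collapse_with_masks(
    reads: Iterable[ReadRecord], min_base_q: int = 20
) -> dict[str, list[MaskedGroup]]:
    """Collapse per library by (sequence, positions below ``min_base_q``)."""
    thresh = chr(min_base_q + DEFAULT_PHRED_OFFSET)
    table: dict[str, Counter] = {}
    for r in reads:
        lowq = tuple(i for i, q in enumerate(r.quality) if q < thresh)
        table.setdefault(r.library, Counter())[(r.sequence, lowq)] += 1
    return {
        lib: [MaskedGroup(seq, lowq, c) for (seq, lowq), c in sorted(cnt.items())]
        for lib, cnt in sorted(table.items())
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_collapsed_fasta(collapsed: Sequence[CollapsedRead], path: str | Path) -> None:
    """FASTA with ``>seq<rank>_x<count>`` headers, ranked by total count."""
    ranked = sorted(collapsed, key=lambda c: (-c.total, c.sequence))
    with open(path, "w") as fh:
        for rank, c in enumerate(ranked, 1):
            fh.write(f">seq{rank}_x{c.total}\n{c.sequence}\n")


def write_count_table(collapsed: Sequence[CollapsedRead], path: str | Path) -> None:
    libs = sorted({lib for c in collapsed for lib in c.counts})
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(libs) + "\n")
        for c in collapsed:
            fh.write(c.sequence + "\t" + "\t".join(str(c.counts.get(l, 0)) for l in libs) + "\n")


def read_count_table(path: str | Path) -> list[CollapsedRead]:
    out = []
    with open(path) as fh:
        libs = fh.readline().rstrip("\n").split("\t")[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {l: int(v) for l, v in zip(libs, parts[1:]) if int(v) > 0}
            out.append(CollapsedRead(parts[0], counts))
    return out
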