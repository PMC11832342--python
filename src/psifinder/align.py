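"""Desk-scale read placement on the toy reference.

End-to-end (ungapped) alignment of collapsed small RNA sequences on
both strands with a configurable mismatch tolerance, plus a variant
that additionally admits exactly one 1-nt internal deletion relative to
the reference — the CMC/Mn²⁺ read-through signature. The contract is
deliberately simple enough to verify against an exhaustive
all-offset/both-strand scan, which the test suite does.

Candidate generation uses pigeonhole seeding: a read aligned with at
most *m* mismatches must contain at least one of *m*+1 disjoint exact
chunks (one extra chunk absorbs the deletion shift), so chunk lookups in
a k-mer index enumerate a superset of all valid placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simdata import ToyReference, revcomp

logger = logging.getLogger("psifinder.align")

POLICIES = ("all_best", "unique_only", "first_best")
# accepted alias: multimapping not allowed == unique_only
_POLICY_ALIASES = {"none_allowed_multimap": "unique_only", "single_hit": "first_best"}


@dataclass(frozen=True)
class Alignment:
    """One end-to-end hit; coordinates 0-based half-open on the + strand."""

    sequence: str
    contig: str
    start: int
    strand: str
    mismatch_read_pos: tuple[int, ...] = ()
    mismatch_ref_pos: tuple[int, ...] = ()
    deletion_ref_pos: int | None = None
    n_best_hits: int = 1
    capped: bool = False

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_read_pos)

    @property
    def n_edits(self) -> int:
        return self.n_mismatch + (self.deletion_ref_pos is not None)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) + (self.deletion_ref_pos is not None)

    def read_pos_to_ref(self, i: int) -> int:
        """Reference position of read base ``i`` (read 5′→3′ coordinates)."""
        L = len(self.sequence)
        j = i if self.strand == "+" else L - 1 - i
        pos = self.start + j
        if self.deletion_ref_pos is not None and pos >= self.deletion_ref_pos:
            pos += 1
        return pos


class RefIndex:
    """k-mer lookup over the reference contigs (built lazily per k)."""

    def __init__(self, ref: ToyReference | dict):
        contigs = ref.contigs if isinstance(ref, ToyReference) else ref
        self.names = sorted(contigs)
        self.seqs = {n: contigs[n] for n in self.names}
        self.arrs = {n: np.frombuffer(contigs[n].encode(), dtype=np.uint8)
                     for n in self.names}
        self._kmers: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def kmer_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmers:
            idx: dict[str, list[tuple[str, int]]] = {}
            for name in self.names:
                s = self.seqs[name]
                for p in range(len(s) - k + 1):
                    idx.setdefault(s[p:p + k], []).append((name, p))
            self._kmers[k] = idx
        return self._kmers[k]

    def candidates(self, q: str, n_chunks: int, deletion: bool) -> set[tuple[str, int]]:
        L = len(q)
        k = L // n_chunks
        if k < 4:  # short read: exhaustive offsets
            cands = set()
            for name in self.names:
                top = len(self.seqs[name]) - L + (1 if deletion else 0)
                cands.update((name, s) for s in range(max(top, 0) + 1))
            return cands
        idx = self.kmer_index(k)
        cands: set[tuple[str, int]] = set()
        for c in range(n_chunks):
            o = c * k
            for name, p in idx.get(q[o:o + k], ()):
                cands.add((name, p - o))
                if deletion:
                    cands.add((name, p - o - 1))
        return cands


_HitKey = tuple[int, int]  # (total edits, number of deletions)


def _scan_strand(index: RefIndex, q: str, max_mismatch: int, deletion: bool):
    """Hits of oriented query ``q`` on the forward reference.

    Yields (contig, start, key, mm_ref_offsets, del_ref_pos) where
    mm_ref_offsets are query-array offsets of mismatching bases.
    """
    L = len(q)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    n_chunks = max_mismatch + (2 if deletion else 1)
    for name, s in sorted(index.candidates(q, n_chunks, deletion)):
        arr = index.arrs[name]
        if s < 0:
            continue
        best = None  # (key, mm_offsets, del_pos)
        if s + L <= len(arr):
            mm = np.flatnonzero(arr[s:s + L] != qa)
            if len(mm) <= max_mismatch:
                best = ((len(mm), 0), mm, None)
        if deletion and s + L + 1 <= len(arr):
            pre = np.concatenate(([0], np.cumsum(arr[s:s + L] != qa)))
            mis2 = arr[s + 1:s + L + 1] != qa
            suf = np.concatenate((np.cumsum(mis2[::-1])[::-1], [0]))
            totals = pre[1:L] + suf[1:L]  # deletion after j query bases, j=1..L-1
            if len(totals):
                j = int(np.argmin(totals))  # leftmost minimum → leftmost deletion
                tot = int(totals[j])
                jq = j + 1
                key = (tot + 1, 1)
                if tot <= max_mismatch and (best is None or key < best[0]):
                    mm = np.concatenate((
                        np.flatnonzero(arr[s:s + jq] != qa[:jq]),
                        jq + np.flatnonzero(arr[s + jq + 1:s + L + 1] != qa[jq:]),
                    ))
                    best = (key, mm, s + jq)
        if best is not None:
            yield name, s, best[0], best[1], best[2]


def _align_one(index: RefIndex, seq: str, max_mismatch: int,
               deletion: bool) -> list[Alignment]:
    """All best-stratum hits of one sequence, deterministically ordered."""
    L = len(seq)
    raw: list[tuple[_HitKey, tuple, Alignment]] = []
    rc = revcomp(seq)
    # a palindromic read places identically on both strands; scan once
    strands = (("+", seq),) if rc == seq else (("+", seq), ("-", rc))
    for strand, q in strands:
        for contig, s, key, mm_off, del_pos in _scan_strand(index, q, max_mismatch, deletion):
            if strand == "+":
                read_pos = tuple(int(i) for i in mm_off)
            else:
                read_pos = tuple(sorted(L - 1 - int(i) for i in mm_off))
            ref_pos = []
            for i in mm_off:
                p = s + int(i)
                if del_pos is not None and p >= del_pos:
                    p += 1
                ref_pos.append(p)
            aln = Alignment(seq, contig, s, strand, read_pos, tuple(sorted(ref_pos)),
                            del_pos)
            raw.append((key, (contig, s, strand), aln))
    if not raw:
        return []
    best_key = min(k for k, _, _ in raw)
    hits = sorted(((o, a) for k, o, a in raw if k == best_key))
    n = len(hits)
    return [replace(a, n_best_hits=n) for _, a in hits]


def _resolve_policy(policy: str) -> str:
    policy = _POLICY_ALIASES.get(policy, policy)
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    return policy


def _sequences(queries: Iterable) -> list[str]:
    out = []
    for q in queries:
        out.append(q if isinstance(q, str) else q.sequence)
    return out


def align_reads(
    queries: Iterable,
    ref: ToyReference | RefIndex | dict,
    max_mismatch: int = 1,
    policy: str = "all_best",
    hit_cap: int = 50,
) -> list[Alignment]:
    """Ungapped end-to-end alignment of unique sequences.

    For each sequence, all hits on either strand in the best stratum
    (fewest mismatches) are found; ``policy`` then selects ``all_best``
    (every best hit), ``unique_only`` (drop sequences whose best stratum
    holds more than one hit) or ``first_best`` (one deterministic hit
    per sequence, for single-mapping-event analyses). Unmapped
    sequences are dropped; sequences exceeding ``hit_cap`` best hits
    are flagged ``capped`` and excluded from unique-only output.
    """
    if not (0 <= max_mismatch <= 3):
        raise ValueError("max_mismatch must be in 0..3")
    policy = _resolve_policy(policy)
    index = ref if isinstance(ref, RefIndex) else RefIndex(ref)
    out: list[Alignment] = []
    for seq in _sequences(queries):
        hits = _align_one(index, seq, max_mismatch, deletion=False)
        out.extend(_apply_policy(hits, policy, hit_cap))
    return out


def align_with_deletions(
    queries: Iterable,
    ref: ToyReference | RefIndex | dict,
    max_mismatch: int = 1,
    policy: str = "all_best",
    hit_cap: int = 50,
) -> list[Alignment]:
    """Alignment additionally admitting one 1-nt internal deletion.

    The best stratum minimises total edits (a deletion counts as one
    edit); at equal edit count a mismatch-only placement is preferred
    over a deletion-bearing one, and ambiguous deletion placements
    (homopolymers) are normalised to the leftmost reference position.
    """
    if not (0 <= max_mismatch <= 3):
        raise ValueError("max_mismatch must be in 0..3")
    policy = _resolve_policy(policy)
    index = ref if isinstance(ref, RefIndex) else RefIndex(ref)
    out: list[Alignment] = []
    for seq in _sequences(queries):
        hits = _align_one(index, seq, max_mismatch, deletion=True)
        out.extend(_apply_policy(hits, policy, hit_cap))
    return out


def _apply_policy(hits: list[Alignment], policy: str, hit_cap: int) -> list[Alignment]:
    if not hits:
        return []
    n = hits[0].n_best_hits
    if n > hit_cap:
        if policy == "unique_only":
            return []
        hits = [replace(a, capped=True) for a in hits[:hit_cap]]
        return hits[:1] if policy == "first_best" else hits
    if policy == "unique_only":
        return hits if n == 1 else []
    if policy == "first_best":
        return hits[:1]
    return hits


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def feature_trees(ref: ToyReference) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in ref.features:
        trees.setdefault(f.contig, IntervalTree())[f.start:f.end] = f
    return trees


def annotate_alignments(
    alignments: Sequence[Alignment],
    ref: ToyReference,
    min_overlap_frac: float = 0.8,
) -> pd.DataFrame:
    """Per-sequence annotation table from alignment hits.

    A hit is assigned to every feature covering at least
    ``min_overlap_frac`` of the aligned span. Columns: sorted feature
    ids, their classes, TE families and gene-set labels, sequence
    length and the hit count.
    """
    trees = feature_trees(ref)
    per_seq: dict[str, dict] = {}
    for a in alignments:
        rec = per_seq.setdefault(a.sequence, {
            "features": set(), "classes": set(), "families": set(),
            "gene_sets": set(), "n_hits": 0})
        rec["n_hits"] += 1
        tree = trees.get(a.contig)
        if tree is None:
            continue
        span = a.end - a.start
        for iv in tree[a.start:a.end]:
            overlap = min(iv.end, a.end) - max(iv.begin, a.start)
            if overlap >= min_overlap_frac * span:
                f = iv.data
                rec["features"].add(f.id)
                rec["classes"].add(f.cls)
                if f.family:
                    rec["families"].add(f.family)
                rec["gene_sets"].update(f.gene_sets)
    rows = []
    for seq in sorted(per_seq):
        rec = per_seq[seq]
        rows.append({
            "sequence": seq,
            "length": len(seq),
            "features": ",".join(sorted(rec["features"])),
            "classes": ",".join(sorted(rec["classes"])),
            "families": ",".join(sorted(rec["families"])),
            "gene_sets": ",".join(sorted(rec["gene_sets"])),
            "n_hits": rec["n_hits"],
        })
    return pd.DataFrame(rows).set_index("sequence") if rows else pd.DataFrame(
        columns=["length", "features", "classes", "families", "gene_sets", "n_hits"])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_alignment_table(alignments: Sequence[Alignment], path: str | Path) -> None:
    rows = [{
        "sequence": a.sequence, "contig": a.contig, "start": a.start,
        "end": a.end, "strand": a.strand,
        "n_mismatch": a.n_mismatch,
        "mismatch_read_pos": ",".join(map(str, a.mismatch_read_pos)),
        "deletion_ref_pos": "" if a.deletion_ref_pos is None else a.deletion_ref_pos,
        "n_best_hits": a.n_best_hits, "capped": int(a.capped),
    } for a in alignments]
    pd.DataFrame(rows, columns=[
        "sequence", "contig", "start", "end", "strand", "n_mismatch",
        "mismatch_read_pos", "deletion_ref_pos", "n_best_hits", "capped",
    ]).to_csv(path, sep="\t", index=False)


def write_sam(alignments: Sequence[Alignment], ref: ToyReference,
              path: str | Path) -> None:
    """Valid minimal SAM with NM and an XD tag for the deletion site."""
    import pysam

    names = sorted(ref.contigs)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": len(ref.contigs[n])} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, a in enumerate(alignments):
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = f"aln{i + 1}"
            fwd = a.sequence if a.strand == "+" else revcomp(a.sequence)
            seg.query_sequence = fwd
            seg.flag = 0 if a.strand == "+" else 16
            seg.reference_id = tid[a.contig]
            seg.reference_start = a.start
            seg.mapping_quality = 255
            if a.deletion_ref_pos is None:
                seg.cigartuples = [(0, len(a.sequence))]
            else:
                lead = a.deletion_ref_pos - a.start
                seg.cigartuples = [(0, lead), (2, 1), (0, len(a.sequence) - lead)]
            tags = [("NM", a.n_edits), ("XH", a.n_best_hits)]
            if a.deletion_ref_pos is not None:
                tags.append(("XD", a.deletion_ref_pos + 1))  # 1-based for reports
            seg.tags = tags
            fh.write(seg)
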