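"""Nucleotide-resolution Ψ inference from Mn²⁺ read-through libraries.

The Mn²⁺ reverse transcriptase converts CMC adducts at Ψ into 1-nt
deletions or non-cognate base calls. This module re-implements the
pileup stage over the deletion-aware alignments, applies the
mismatch-ratio calling rule (a site is called when the treated library
shows at least ``min_reads`` coverage and the treated/mock ratio of
altered-call fractions is at least ``min_fold``), summarizes calls as
positional metaprofiles relative to the feature ends, validates planted
rRNA sites by paired coverage depletion, and intersects the three
assays into consensus support classes.

"Altered" counts mismatches plus 1-nt deletions at a reference
position; base calls below a Phred threshold (when the caller supplies
per-read quality masks) are excluded from both coverage and altered
counts, as is deletion evidence flanked by low-quality bases.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment
from .simdata import ToyReference

logger = logging.getLogger("psifinder.sitecall")

DEFAULT_MIN_READS = 5     # minimum treated coverage per site/feature
DEFAULT_MIN_FOLD = 1.5    # minimum treated/mock altered-ratio fold change


@dataclass
class PileupProfile:
    """Per-position coverage / altered / read-end counts for one library."""

    coverage: dict[tuple[str, int], int] = field(default_factory=dict)
    altered: dict[tuple[str, int], int] = field(default_factory=dict)
    end5: dict[tuple[str, int], int] = field(default_factory=dict)
    end3: dict[tuple[str, int], int] = field(default_factory=dict)

    def validate(self) -> None:
        for key, alt in self.altered.items():
            if alt > self.coverage.get(key, 0):
                raise AssertionError(f"altered > coverage at {key}")

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.coverage)
        return pd.DataFrame({
            "contig": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "coverage": [self.coverage[k] for k in keys],
            "altered": [self.altered.get(k, 0) for k in keys],
            "end5": [self.end5.get(k, 0) for k in keys],
            "end3": [self.end3.get(k, 0) for k in keys],
        })

    def add(self, other: "PileupProfile") -> "PileupProfile":
        out = PileupProfile()
        for name in ("coverage", "altered", "end5", "end3"):
            merged = dict(getattr(self, name))
            for k, v in getattr(other, name).items():
                merged[k] = merged.get(k, 0) + v
            setattr(out, name, merged)
        return out


def build_pileup(
    groups: Iterable[tuple[Alignment, int, tuple[int, ...]]],
    ref: ToyReference | None = None,
    min_base_q_masking: bool = True,
) -> PileupProfile:
    """Accumulate a pileup from (alignment, read count, low-quality read
    positions) groups.

    Mismatches and the deleted reference base increment ``altered``.
    Masked (low-quality) base calls are excluded from coverage, and a
    read carrying any masked base contributes no altered evidence at
    all: a read with several miscalls can be re-placed by the
    deletion-aware aligner in a way that converts quality-flagged
    errors into ostensibly clean edits, so Ψ evidence is restricted to
    reads whose every base passes the quality threshold.
    """
    prof = PileupProfile()
    contigs = set(ref.contigs) if ref is not None else None
    cov, alt, e5, e3 = prof.coverage, prof.altered, prof.end5, prof.end3
    for aln, count, lowq in groups:
        if contigs is not None and aln.contig not in contigs:
            raise KeyError(f"alignment references unknown contig {aln.contig}")
        L = len(aln.sequence)
        mask = set(lowq) if min_base_q_masking else set()
        c = aln.contig
        clean = not mask
        for i in range(L):
            if i in mask:
                continue
            key = (c, aln.read_pos_to_ref(i))
            cov[key] = cov.get(key, 0) + count
        if clean:
            for rp in aln.mismatch_ref_pos:
                key = (c, rp)
                alt[key] = alt.get(key, 0) + count
        if aln.deletion_ref_pos is not None:
            key = (c, aln.deletion_ref_pos)
            cov[key] = cov.get(key, 0) + count
            if clean:
                alt[key] = alt.get(key, 0) + count
        # strand-aware terminal flags
        p5 = aln.read_pos_to_ref(0)
        p3 = aln.read_pos_to_ref(L - 1)
        e5[(c, p5)] = e5.get((c, p5), 0) + count
        e3[(c, p3)] = e3.get((c, p3), 0) + count
    prof.validate()
    return prof


def pileup_from_masked_groups(
    alignments: Sequence[Alignment],
    masked_groups: Sequence,
    **kw,
) -> PileupProfile:
    """Convenience: join MaskedGroups of one library with their alignments.

    ``alignments`` must be single-hit per sequence (``unique_only`` or
    ``first_best`` policy); groups whose sequence did not align are
    skipped.
    """
    by_seq: dict[str, Alignment] = {}
    for a in alignments:
        by_seq.setdefault(a.sequence, a)
    triples = []
    for g in masked_groups:
        a = by_seq.get(g.sequence)
        if a is not None:
            triples.append((a, g.count, g.lowq))
    return build_pileup(triples, **kw)


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def call_psi_sites(
    treated: PileupProfile,
    mock: PileupProfile,
    min_reads: int = DEFAULT_MIN_READS,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_mock_cov: int = DEFAULT_MIN_READS,
    pseudo: str = "add",
    min_alt: int = 1,
) -> pd.DataFrame:
    """Per-position Ψ calls from a treated/mock pileup pair.

    A position is called when treated coverage >= ``min_reads``, the
    treated library shows at least ``min_alt`` altered reads (without
    this, the pseudocount ratio degenerates to a coverage ratio at
    evidence-free positions), and the pseudocount-regularized ratio of
    altered fractions ``(r_t + 0.5/cov_t) / (r_m + 0.5/cov_m)`` is
    >= ``min_fold``. ``pseudo="exclude_zero_mock"`` instead drops
    positions whose mock shows no altered call (reported untestable).
    Positions with mock coverage below ``min_mock_cov`` are reported as
    untestable.
    """
    if pseudo not in ("add", "exclude_zero_mock"):
        raise ValueError("pseudo must be 'add' or 'exclude_zero_mock'")
    rows = []
    for key in sorted(treated.coverage):
        contig, pos = key
        ct = treated.coverage[key]
        at = treated.altered.get(key, 0)
        cm = mock.coverage.get(key, 0)
        am = mock.altered.get(key, 0)
        rt = at / ct if ct else 0.0
        rm = am / cm if cm else 0.0
        testable = cm >= min_mock_cov
        fold = np.nan
        called = False
        if testable:
            if pseudo == "add":
                fold = (rt + 0.5 / ct) / (rm + 0.5 / cm)
            elif am == 0:
                testable = False
            else:
                fold = rt / rm
        if testable:
            called = bool(ct >= min_reads and at >= min_alt and fold >= min_fold)
        rows.append((contig, pos, ct, at, rt, cm, am, rm, fold, testable, called))
    return pd.DataFrame(rows, columns=[
        "contig", "pos", "reads_treated", "altered_treated", "ratio_treated",
        "reads_mock", "altered_mock", "ratio_mock", "fold_change",
        "testable", "called"])


def per_feature_calls(site_calls: pd.DataFrame, ref: ToyReference) -> pd.DataFrame:
    """Feature-level rollup: the maximum fold change over a feature's
    testable positions decides the call; the winning position and its
    within-feature 5′ offset are reported alongside."""
    rows = []
    for f in ref.features:
        sub = site_calls[(site_calls.contig == f.contig)
                         & (site_calls.pos >= f.start) & (site_calls.pos < f.end)]
        sub = sub[sub.testable]
        if sub.empty:
            continue
        best = sub.loc[sub.fold_change.idxmax()]
        off = int(best.pos - f.start if f.strand == "+" else f.end - 1 - best.pos)
        rows.append({
            "feature": f.id, "cls": f.cls, "contig": f.contig,
            "pos": int(best.pos), "offset": off,
            "reads_treated": int(best.reads_treated),
            "fold_change": float(best.fold_change),
            "called": bool(sub.called.any()),
        })
    return pd.DataFrame(rows, columns=[
        "feature", "cls", "contig", "pos", "offset", "reads_treated",
        "fold_change", "called"]).set_index("feature")


# ---------------------------------------------------------------------------
# Positional metaprofile
# ---------------------------------------------------------------------------

def positional_metaprofile(
    calls: pd.DataFrame,
    ref: ToyReference,
    classes: Sequence[str] = ("miRNA",),
    k: int = 10,
) -> pd.DataFrame:
    """Modification frequency by distance from the feature ends.

    For offsets 0..k-1 from the 5′ end and −1..−k from the 3′ end, the
    fraction of features with a called site at that offset, normalized
    by the number of features that expose a U at the offset. Input is
    the per-position call table.
    """
    feats = [f for f in ref.features if f.cls in classes]
    called = set()
    for _, row in calls[calls.called].iterrows():
        called.add((row.contig, int(row.pos)))
    rows = []
    for side in ("5p", "3p"):
        for d in range(k):
            n_u = 0
            n_called = 0
            for f in feats:
                if f.length <= d:
                    continue
                off = d if side == "5p" else f.length - 1 - d
                seq = ref.feature_seq(f)
                if seq[off] != "T":
                    continue
                n_u += 1
                pos = f.start + off if f.strand == "+" else f.end - 1 - off
                if (f.contig, pos) in called:
                    n_called += 1
            label = d + 1 if side == "5p" else -(d + 1)
            rows.append({"end": side, "position": label, "n_u_features": n_u,
                         "n_called": n_called,
                         "frequency": n_called / n_u if n_u else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rRNA known-site validation
# ---------------------------------------------------------------------------

def rrna_site_validation(
    coverage_by_library: Mapping[str, np.ndarray],
    interval: tuple[str, int, int],
    known_sites: Sequence[tuple[str, int]],
    pairs: Sequence[tuple[str, str]],
    window: int = 2,
) -> tuple[pd.Series, pd.DataFrame]:
    """Paired coverage depletion around known rRNA Ψ sites.

    ``coverage_by_library`` maps library label → per-position coverage
    over the locus interval (0-based, length ``end − start``). Each
    library's coverage is normalized to its total coverage across the
    locus; the per-position log2 of the treated/reference ratio is
    averaged over the given pairs (technical replicates), and the mean
    over ±``window`` positions around each known site is returned
    together with the full locus track. Depletion is negative.
    """
    contig, start, end = interval
    L = end - start
    norm = {}
    for lib, cov in coverage_by_library.items():
        cov = np.asarray(cov, dtype=float)
        if len(cov) != L:
            raise ValueError(f"coverage track for {lib} has wrong length")
        total = cov.sum()
        if total <= 0:
            raise ValueError(f"zero locus coverage in library {lib}")
        # depth-free pseudo-share keeps uncovered positions finite in the
        # log while leaving the track exactly invariant to depth rescaling
        norm[lib] = cov / total + 0.5 / L
    tracks = []
    for t_lib, r_lib in pairs:
        tracks.append(np.log2(norm[t_lib] / norm[r_lib]))
    track = np.mean(tracks, axis=0)
    site_means = {}
    for c, pos in known_sites:
        if c != contig or not (start <= pos < end):
            raise ValueError(f"known site {c}:{pos} outside the locus interval")
        i = pos - start
        lo, hi = max(0, i - window), min(L, i + window + 1)
        site_means[f"{c}:{pos + 1}"] = float(track[lo:hi].mean())  # 1-based label
    frame = pd.DataFrame({"contig": contig, "pos": np.arange(start, end),
                          "log2fc": track})
    return pd.Series(site_means, name="mean_log2fc"), frame


def coverage_track(
    alignments: Sequence[Alignment],
    counts: Mapping[str, int],
    interval: tuple[str, int, int],
) -> np.ndarray:
    """Per-position coverage of one library over a locus interval."""
    contig, start, end = interval
    track = np.zeros(end - start)
    for a in alignments:
        if a.contig != contig:
            continue
        n = counts.get(a.sequence, 0)
        if n == 0:
            continue
        lo, hi = max(a.start, start), min(a.end, end)
        if lo < hi:
            track[lo - start:hi - start] += n
    return track


# ---------------------------------------------------------------------------
# Three-assay consensus
# ---------------------------------------------------------------------------

def consensus_calls(
    ip_results: pd.DataFrame,
    cmc_results: pd.DataFrame,
    mn_calls: pd.DataFrame,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-feature assay support and Venn class sizes.

    Support criteria: IP — ``padj < alpha`` with positive log2FC
    (enriched in the bound fraction); CMC — ``padj < alpha`` with
    negative log2FC (depleted after CMC); MnCMC — a called site. The
    intersection of all three is the high-confidence set.
    """
    features = sorted(set(ip_results.index) | set(cmc_results.index) | set(mn_calls.index))
    rows = []
    for fid in features:
        ip = (fid in ip_results.index
              and ip_results.loc[fid, "padj"] < alpha and ip_results.loc[fid, "log2FC"] > 0)
        cmc = (fid in cmc_results.index
               and cmc_results.loc[fid, "padj"] < alpha and cmc_results.loc[fid, "log2FC"] < 0)
        mn = fid in mn_calls.index and bool(mn_calls.loc[fid, "called"])
        support = [name for name, flag in (("IP", ip), ("CMC", cmc), ("MnCMC", mn)) if flag]
        rows.append({"feature": fid, "IP": bool(ip), "CMC": bool(cmc), "MnCMC": bool(mn),
                     "support": "&".join(support) if support else "none",
                     "high_confidence": bool(ip and cmc and mn)})
    table = pd.DataFrame(rows).set_index("feature")
    venn: dict[str, int] = defaultdict(int)
    for _, r in table.iterrows():
        venn[r.support] += 1
    venn["IP&CMC&MnCMC"] = int(table.high_confidence.sum())
    return table, dict(venn)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_site_table(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["pos_1based"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(track: pd.DataFrame, path: str | Path, value_col: str = "log2fc") -> None:
    with open(path, "w") as fh:
        for _, row in track.iterrows():
            fh.write(f"{row.contig}\t{int(row.pos)}\t{int(row.pos) + 1}\t{row[value_col]:.6g}\n")
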