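"""Feature-level rollups of per-sequence enrichment results.

Covers the aggregation analyses downstream of the enrichment tests:
transposon-family × size-class mean fold changes, Argonaute (AGO)
preference assignment across AGO-IP libraries, terminal-nucleotide
composition of Ψ-status groups, tRNA-fragment (tRF) classification, and
gene-set metagene coverage profiles with fixed upstream/body/downstream
binning and moving-average smoothing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment
from .simdata import Feature, ToyReference

logger = logging.getLogger("psifinder.aggregate")

DEFAULT_SIZE_CLASSES = ((20, 22), (23, 25))


def _size_class(length: int, classes: Sequence[tuple[int, int]]) -> str | None:
    for lo, hi in classes:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return None


def average_replicates(values: pd.DataFrame, tech_of: Mapping[str, str]) -> pd.Series:
    """Two-stage replicate averaging: technical replicates of one
    biological replicate are averaged first, then biological replicates.
    ``tech_of`` maps column → biological replicate id. On unbalanced
    designs this differs from pooling all columns."""
    bio_groups: dict[str, list[str]] = {}
    for col in values.columns:
        bio_groups.setdefault(tech_of[col], []).append(col)
    bio_means = pd.concat(
        [values.loc[:, cols].mean(axis=1) for cols in bio_groups.values()], axis=1)
    return bio_means.mean(axis=1)


def aggregate_family_enrichment(
    enrichment: pd.DataFrame,
    annot: pd.DataFrame,
    size_classes: Sequence[tuple[int, int]] = DEFAULT_SIZE_CLASSES,
    min_cluster_mean: float = 0.0,
    counts: pd.DataFrame | None = None,
    weight: str = "once_per_family",
) -> pd.DataFrame:
    """Mean log2FC per TE family × size class.

    ``enrichment`` is indexed by sequence with a ``log2FC`` column;
    ``annot`` provides comma-separated ``families`` and ``length``. A
    sequence matching several families contributes once to each
    (``weight="fractional"`` splits its contribution instead). Families
    whose member sequences sum to a mean raw count below
    ``min_cluster_mean`` (requires ``counts``) are excluded.
    """
    rows = []
    for seq in enrichment.index:
        if seq not in annot.index:
            continue
        fams = [f for f in str(annot.loc[seq, "families"]).split(",") if f]
        if not fams:
            continue
        sc = _size_class(int(annot.loc[seq, "length"]), size_classes)
        if sc is None:
            continue
        w = 1.0 / len(fams) if weight == "fractional" else 1.0
        for fam in fams:
            rows.append((fam, sc, seq, float(enrichment.loc[seq, "log2FC"]), w))
    if not rows:
        return pd.DataFrame(columns=["family", "size_class", "mean_log2FC", "n"])
    df = pd.DataFrame(rows, columns=["family", "size_class", "seq", "log2FC", "w"])
    if min_cluster_mean > 0:
        if counts is None:
            raise ValueError("min_cluster_mean requires the raw count matrix")
        fam_means = {
            fam: counts.loc[[s for s in sub.seq.unique() if s in counts.index]].sum().mean()
            for fam, sub in df.groupby("family")
        }
        df = df[df.family.map(fam_means) >= min_cluster_mean]
    out = (df.groupby(["family", "size_class"])
             .apply(lambda g: pd.Series({
                 "mean_log2FC": np.average(g.log2FC, weights=g.w),
                 "n": len(g)}), include_groups=False)
             .reset_index())
    out["n"] = out["n"].astype(int)
    return out


def assign_ago_preference(enrichment_by_ago: pd.DataFrame) -> pd.DataFrame:
    """Preferred AGO per family × size class (argmax enrichment).

    Input: rows indexed by (family, size_class), one column per AGO-IP
    library. Exact ties are labelled "ambiguous". The result also
    reports per-AGO preferred-family counts in ``.attrs['counts']``.
    """
    if enrichment_by_ago.shape[1] < 2:
        raise ValueError("need at least two AGO libraries")
    cols = list(enrichment_by_ago.columns)
    prefs = []
    for _, row in enrichment_by_ago.iterrows():
        vals = row.to_numpy(dtype=float)
        top = vals.max()
        winners = [c for c, v in zip(cols, vals) if v == top]
        prefs.append(winners[0] if len(winners) == 1 else "ambiguous")
    out = enrichment_by_ago.copy()
    out["preferred_ago"] = prefs
    out.attrs["counts"] = dict(pd.Series(prefs).value_counts().sort_index())
    return out


def terminal_nt_composition(
    groups: Mapping[str, Iterable[str]],
    annot: pd.DataFrame | None = None,
    exclude_classes: Sequence[str] = ("tRNA", "rRNA"),
) -> pd.DataFrame:
    """5′/3′ base frequencies per sequence group (RNA alphabet, U for T).

    ``groups`` maps a label (e.g. "psi", "background") to sequences.
    Sequences annotated to an excluded structural-RNA class are removed
    before counting. Frequencies sum to 1 per group and position.
    """
    rows = []
    for label, seqs in sorted(groups.items()):
        kept = []
        for s in seqs:
            if annot is not None and s in annot.index:
                classes = set(str(annot.loc[s, "classes"]).split(","))
                if classes & set(exclude_classes):
                    continue
            kept.append(s)
        for end, idx in (("5p", 0), ("3p", -1)):
            counts = {"A": 0, "C": 0, "G": 0, "U": 0}
            for s in kept:
                b = s[idx].replace("T", "U")
                if b in counts:
                    counts[b] += 1
            total = sum(counts.values())
            for b, n in counts.items():
                rows.append({"group": label, "end": end, "base": b,
                             "frequency": n / total if total else 0.0, "n": total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tRNA fragments
# ---------------------------------------------------------------------------

UNUAR_RE = re.compile("T.TA[AG]")  # UNUAR on the DNA alphabet


def extract_trfs(
    alignments: Sequence[Alignment],
    ref: ToyReference,
    psi55_offset: int = 54,
    end_tolerance: int = 0,
) -> pd.DataFrame:
    """Classify reads mapping within tRNAs as 5′-tRF, 3′-tRF or internal.

    A 3′-tRF's read 3′ end coincides with the tRNA's 3′ (CCA) end; a
    5′-tRF's read 5′ end coincides with the tRNA start (both within
    ``end_tolerance``). Flags mark reads containing the UNUAR motif
    (U-N-U-A-purine, PUS7 substrate) and reads spanning the annotated
    U55 position.
    """
    trnas = [f for f in ref.features if f.cls == "tRNA"]
    rows = []
    for a in alignments:
        for f in trnas:
            if f.contig != a.contig or a.start < f.start or a.end > f.end:
                continue
            if f.strand == "+":
                d5, d3 = a.start - f.start, f.end - a.end
            else:
                d5, d3 = f.end - a.end, a.start - f.start
            if d3 <= end_tolerance:
                cls = "3p_tRF"
            elif d5 <= end_tolerance:
                cls = "5p_tRF"
            else:
                cls = "internal"
            span = (d5 <= psi55_offset < d5 + (a.end - a.start))
            rows.append({
                "sequence": a.sequence, "trna": f.id, "trf_class": cls,
                "unuar": bool(UNUAR_RE.search(a.sequence)),
                "spans_psi55": bool(span),
            })
    return pd.DataFrame(rows, columns=["sequence", "trna", "trf_class", "unuar",
                                       "spans_psi55"])


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Binned coverage over [upstream flank | scaled body | downstream flank]."""

    values: pd.DataFrame          # bins × treatment (or size-class) columns
    n_flank_bins: int
    n_body_bins: int
    window: int
    smooth: int

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated edge windows."""
    if width <= 1:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    half_lo = (width - 1) // 2
    half_hi = width // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half_lo), min(len(x), i + half_hi + 1)
        out[i] = x[lo:hi].mean()
    return out


def genome_coverage(
    alignments: Sequence[Alignment],
    counts: Mapping[str, int],
    contig_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    cov = {name: np.zeros(L) for name, L in contig_lengths.items()}
    for a in alignments:
        n = counts.get(a.sequence, 0)
        if n and a.contig in cov:
            cov[a.contig][a.start:a.end] += n
    return cov


def _rescale(track: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean coverage over n_bins equal fractions of the track."""
    edges = np.linspace(0, len(track), n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = int(np.floor(edges[i])), max(int(np.ceil(edges[i + 1])), int(np.floor(edges[i])) + 1)
        out[i] = track[lo:min(hi, len(track))].mean() if len(track) else 0.0
    return out


def metaplot_profile(
    coverage_by_library: Mapping[str, Mapping[str, np.ndarray]],
    treatment_of: Mapping[str, str],
    genes: Sequence[Feature],
    flank: int = 500,
    body_bins: int = 60,
    window: int = 25,
    smooth: int = 6,
) -> MetaProfile:
    """Metagene coverage profile over a gene set.

    Each library's genome coverage is depth-normalized (divided by its
    total coverage) and libraries are merged (averaged) within
    treatment. Per gene, the upstream flank, the body rescaled to
    ``body_bins`` bins, and the downstream flank are stitched
    strand-aware (minus-strand genes reversed); flanks are binned at the
    ``window`` size; a centered moving average of width ``smooth`` is
    applied to the gene-averaged profile. Flanks running off a contig
    end are truncated (with a warning) and ignored in the average.
    """
    if flank % window:
        raise ValueError("flank must be a multiple of the window size")
    n_flank_bins = flank // window
    merged: dict[str, dict[str, np.ndarray]] = {}
    for lib, tracks in coverage_by_library.items():
        total = sum(t.sum() for t in tracks.values())
        if total <= 0:
            raise ValueError(f"library {lib} has zero coverage")
        t = treatment_of[lib]
        tgt = merged.setdefault(t, {c: np.zeros(len(v)) for c, v in tracks.items()})
        for c, v in tracks.items():
            tgt[c] += v / total
    for t, tracks in merged.items():
        n_libs = sum(1 for l in coverage_by_library if treatment_of[l] == t)
        for c in tracks:
            tracks[c] /= n_libs

    columns = {}
    for treatment in sorted(merged):
        tracks = merged[treatment]
        per_gene = []
        for g in genes:
            track = tracks.get(g.contig)
            if track is None:
                continue
            up = track[max(0, g.start - flank):g.start]
            down = track[g.end:g.end + flank]
            if len(up) < flank or len(down) < flank:
                logger.warning("gene %s flank truncated at contig end", g.id)
                up = np.pad(up, (flank - len(up), 0), constant_values=np.nan)
                down = np.pad(down, (0, flank - len(down)), constant_values=np.nan)
            body = track[g.start:g.end]
            if g.strand == "-":
                up, down = down[::-1], up[::-1]
                body = body[::-1]
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN flank bins
                up_b = np.nanmean(up.reshape(n_flank_bins, window), axis=1)
                down_b = np.nanmean(down.reshape(n_flank_bins, window), axis=1)
            per_gene.append(np.concatenate([up_b, _rescale(body, body_bins), down_b]))
        if not per_gene:
            raise ValueError("no gene lies on the covered contigs")
        stacked = np.vstack(per_gene)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
            prof = np.nanmean(stacked, axis=0)
        columns[treatment] = moving_average(np.nan_to_num(prof), smooth)
    n_bins = 2 * n_flank_bins + body_bins
    region = (["upstream"] * n_flank_bins + ["body"] * body_bins
              + ["downstream"] * n_flank_bins)
    values = pd.DataFrame(columns, index=pd.RangeIndex(n_bins, name="bin"))
    values.insert(0, "region", region)
    return MetaProfile(values, n_flank_bins, body_bins, window, smooth)
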