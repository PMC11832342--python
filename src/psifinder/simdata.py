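"""Synthetic small RNA-seq data with known pseudouridine (Ψ) ground truth.

This module builds a scale-reduced toy reference (miRNA, transposon,
rRNA, tRNA and unclassified loci), plants Ψ sites with per-site
stoichiometry, and simulates sequencing libraries for the three
detection chemistries at the molecule level:

* **Ψ-IP** — antibody capture of Ψ-bearing molecules with a background
  capture rate for unmodified molecules; bound and unbound fractions are
  emitted separately and conserve the input molecule count exactly.
* **CMC / standard RT** — each Ψ on a molecule receives a bulky CMC
  adduct with probability ``adduct_prob``; under standard reverse
  transcription any molecule carrying at least one adduct terminates
  early and yields a fragment too short to map, so it is dropped from
  the library (depletion readout).
* **CMC / Mn²⁺ RT** — the polymerase reads through adducts, converting
  each one into a 1-nt deletion (``p_del``), a non-cognate base call
  (``p_mis``), or a clean read-through.

A uniform per-base miscall rate is applied last to every library; bases
altered by the miscall process carry reduced Phred quality so that
quality-aware downstream steps behave deterministically.

All randomness flows from ``SimConfig.master_seed`` through named
substreams, so identical configurations produce byte-identical FASTQ
output.
"""

from __future__ import annotations

import gzip
import itertools
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("psifinder.simdata")

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

HIGH_Q_CHAR = "I"  # Phred 40
LOW_Q_CHAR = "#"   # Phred 2, marks an injected miscall


class ConfigError(ValueError):
    """Raised for contradictory or invalid simulation configuration."""


class SimulationError(RuntimeError):
    """Raised when simulation inputs are inconsistent (e.g. off-reference Ψ site)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant child stream of the master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

FEATURE_CLASSES = ("miRNA", "TE_copy", "rRNA", "tRNA", "other")


@dataclass(frozen=True)
class Feature:
    """Annotated interval on the toy genome (0-based, half-open)."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    cls: str
    family: str = ""
    gene_sets: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ToyReference:
    """Toy genome: contig sequences plus feature annotations.

    Contig strings use the DNA alphabet (U is represented as T). The
    rRNA-like contig carries a designated list of "known" Ψ positions
    emulating predicted rRNA pseudouridylation sites.
    """

    contigs: dict[str, str]
    features: list[Feature]
    known_rrna_sites: list[tuple[str, int]] = field(default_factory=list)

    def feature_seq(self, feat: Feature) -> str:
        s = self.contigs[feat.contig][feat.start:feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set(BASES):
                raise ConfigError(f"contig {name} contains non-ACGT characters")
        for f in self.features:
            if f.contig not in self.contigs:
                raise ConfigError(f"feature {f.id} on unknown contig {f.contig}")
            if not (0 <= f.start < f.end <= len(self.contigs[f.contig])):
                raise ConfigError(f"feature {f.id} interval outside contig")
            if f.strand not in "+-":
                raise ConfigError(f"feature {f.id} has invalid strand {f.strand!r}")
            if f.cls not in FEATURE_CLASSES:
                raise ConfigError(f"feature {f.id} has unknown class {f.cls!r}")
            if f.cls == "TE_copy" and not f.family:
                raise ConfigError(f"TE copy {f.id} lacks a family label")
            if f.cls == "tRNA" and not self.feature_seq(f).endswith("CCA"):
                raise ConfigError(f"tRNA {f.id} does not end in CCA on its sense strand")

    # -- I/O ---------------------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_bed(self, path: str | Path) -> None:
        """BED6; the name column carries the family as an ``::`` suffix."""
        rows = sorted(self.features, key=lambda f: (f.contig, f.start, f.id))
        with open(path, "w") as fh:
            for f in rows:
                name = f"{f.id}::{f.family}" if f.family else f.id
                fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


@dataclass
class ClassSpec:
    """Feature count and sense-strand length range for one class."""

    n: int
    min_len: int
    max_len: int


@dataclass
class ReferenceSpec:
    """Counts and length ranges per feature class for the toy genome."""

    mirna: ClassSpec = field(default_factory=lambda: ClassSpec(140, 20, 24))
    te: ClassSpec = field(default_factory=lambda: ClassSpec(30, 60, 90))
    trna: ClassSpec = field(default_factory=lambda: ClassSpec(15, 72, 78))
    other: ClassSpec = field(default_factory=lambda: ClassSpec(14, 25, 60))
    rrna_len: int = 1500
    n_rrna_known_sites: int = 5
    n_te_families: int = 6
    te_divergence: float = 0.03
    mirna_start_u_frac: float = 0.6
    minus_strand_frac: float = 0.3
    n_contigs: int = 2
    spacer_range: tuple[int, int] = (30, 80)
    gene_set_frac: Mapping[str, float] = field(
        default_factory=lambda: {"DME_target": 0.15}
    )

    def validate(self) -> None:
        for cs in (self.mirna, self.te, self.trna, self.other):
            if cs.n < 0:
                raise ConfigError("feature counts must be >= 0")
            if cs.n and not (15 <= cs.min_len <= cs.max_len):
                raise ConfigError("feature lengths must satisfy 15 <= min <= max")
        if self.trna.n and self.trna.min_len < 60:
            raise ConfigError("tRNA features must be at least 60 nt")
        if self.rrna_len and self.rrna_len < 200:
            raise ConfigError("rRNA locus must be at least 200 nt (or 0 to omit)")
        if self.n_contigs < 1:
            raise ConfigError("need at least one contig")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = BASES[(BASES.index(chars[i]) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def build_toy_reference(spec: ReferenceSpec | None = None, seed: int = 0) -> ToyReference:
    """Generate a deterministic toy genome per ``spec``.

    Sense sequences are generated first (tRNAs end in CCA and carry a
    U55/UNUAR block; a configurable fraction of miRNAs starts with U);
    features are then laid out with random spacers on ``n_contigs``
    contigs, with minus-strand features inserted as reverse complements.
    The rRNA locus lives on its own contig and exposes a known-site list.
    """
    spec = spec or ReferenceSpec()
    spec.validate()
    rng = substream(seed, "reference")

    sense: list[tuple[str, str, str, str]] = []  # (id, seq, cls, family)

    for i in range(spec.mirna.n):
        ln = int(rng.integers(spec.mirna.min_len, spec.mirna.max_len + 1))
        seq = _random_seq(rng, ln)
        if rng.random() < spec.mirna_start_u_frac:
            seq = "T" + seq[1:]
        sense.append((f"miR{i + 1:04d}", seq, "miRNA", ""))

    if spec.te.n:
        n_fam = max(1, min(spec.n_te_families, spec.te.n))
        fam_len = [int(rng.integers(spec.te.min_len, spec.te.max_len + 1)) for _ in range(n_fam)]
        fam_seq = [_random_seq(rng, L) for L in fam_len]
        for i in range(spec.te.n):
            fam = i % n_fam
            seq = _mutate(rng, fam_seq[fam], spec.te_divergence)
            sense.append((f"TE{fam + 1}_c{i + 1:03d}", seq, "TE_copy", f"TEfam{fam + 1}"))

    for i in range(spec.trna.n):
        ln = int(rng.integers(spec.trna.min_len, spec.trna.max_len + 1))
        chars = list(_random_seq(rng, ln))
        # TΨC arm block: UNUAR motif with the U55 position at offset 54
        chars[52] = "T"
        chars[54] = "T"
        chars[55] = "A"
        chars[56] = "AG"[rng.integers(0, 2)]
        chars[-3:] = ["C", "C", "A"]
        sense.append((f"tRNA{i + 1:03d}", "".join(chars), "tRNA", ""))

    for i in range(spec.other.n):
        ln = int(rng.integers(spec.other.min_len, spec.other.max_len + 1))
        sense.append((f"locus{i + 1:03d}", _random_seq(rng, ln), "other", ""))

    # layout: round-robin assignment to contigs, sequential with spacers
    contig_parts: list[list[str]] = [[] for _ in range(spec.n_contigs)]
    contig_pos = [0] * spec.n_contigs
    features: list[Feature] = []
    lo, hi = spec.spacer_range
    gene_set_items = sorted(spec.gene_set_frac.items())
    for idx, (fid, seq, cls, fam) in enumerate(sense):
        c = idx % spec.n_contigs
        spacer = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        contig_parts[c].append(spacer)
        contig_pos[c] += len(spacer)
        strand = "-" if rng.random() < spec.minus_strand_frac else "+"
        placed = revcomp(seq) if strand == "-" else seq
        start = contig_pos[c]
        contig_parts[c].append(placed)
        contig_pos[c] += len(seq)
        gsets = tuple(
            label for label, frac in gene_set_items
            if cls in ("TE_copy", "other") and rng.random() < frac
        )
        features.append(Feature(fid, f"chr{c + 1}", start, start + len(seq), strand, cls, fam, gsets))
    for c in range(spec.n_contigs):
        tail = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        contig_parts[c].append(tail)

    contigs = {f"chr{c + 1}": "".join(contig_parts[c]) for c in range(spec.n_contigs)}

    known_sites: list[tuple[str, int]] = []
    if spec.rrna_len:
        pad5 = _random_seq(rng, 50)
        rseq = _random_seq(rng, spec.rrna_len)
        # designated known Ψ positions, forced to U, kept away from the ends
        offs = np.sort(rng.choice(
            np.arange(30, spec.rrna_len - 30), size=spec.n_rrna_known_sites, replace=False))
        chars = list(rseq)
        for o in offs:
            chars[o] = "T"
        rseq = "".join(chars)
        contigs["chrR"] = pad5 + rseq + _random_seq(rng, 50)
        features.append(Feature("rRNA25S", "chrR", 50, 50 + spec.rrna_len, "+", "rRNA"))
        known_sites = [("chrR", 50 + int(o)) for o in offs]

    ref = ToyReference(contigs, features, known_sites)
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# Ψ ground truth
# ---------------------------------------------------------------------------

@dataclass
class PsiGroundTruth:
    """Latent Ψ map: (contig, 0-based position) → stoichiometry in (0, 1]."""

    sites: dict[tuple[str, int], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    def validate(self, ref: ToyReference) -> None:
        for (contig, pos), s in self.sites.items():
            if contig not in ref.contigs or not (0 <= pos < len(ref.contigs[contig])):
                raise SimulationError(f"Ψ site {contig}:{pos} is off the reference")
            if not (0.0 < s <= 1.0):
                raise SimulationError(f"Ψ site {contig}:{pos} stoichiometry {s} outside (0, 1]")
            feats = [f for f in ref.features if f.contig == contig and f.start <= pos < f.end]
            if feats:
                f = feats[0]
                off = pos - f.start if f.strand == "+" else f.end - 1 - pos
                if ref.feature_seq(f)[off] != "T":
                    raise SimulationError(f"Ψ site {contig}:{pos} is not a U on the sense strand")
            elif ref.contigs[contig][pos] != "T":
                raise SimulationError(f"Ψ site {contig}:{pos} is not a U")

    def to_frame(self, ref: ToyReference) -> pd.DataFrame:
        rows = []
        for (contig, pos), s in sorted(self.sites.items()):
            fid, off = "", -1
            for f in ref.features:
                if f.contig == contig and f.start <= pos < f.end:
                    fid = f.id
                    off = pos - f.start if f.strand == "+" else f.end - 1 - pos
                    break
            rows.append((contig, pos, fid, off, s))
        return pd.DataFrame(rows, columns=["contig", "pos", "feature", "offset", "stoichiometry"])

    def write_tsv(self, ref: ToyReference, path: str | Path) -> None:
        self.to_frame(ref).to_csv(path, sep="\t", index=False)


def assign_psi_sites(
    ref: ToyReference,
    frac_modified_features: float | None = None,
    n_modified: int | None = None,
    stoich_range: tuple[float, float] = (0.5, 1.0),
    five_prime_bias: float = 0.0,
    seed: int = 0,
    classes: Sequence[str] = ("miRNA", "TE_copy", "tRNA", "other"),
    sites_per_feature: int = 1,
    rrna_known_stoich: float | None = None,
) -> PsiGroundTruth:
    """Plant Ψ sites on U positions of annotated features.

    Exactly one of ``frac_modified_features`` (independent Bernoulli per
    feature) or ``n_modified`` (exact count, sampled without
    replacement) selects the modified features. ``five_prime_bias`` is
    the probability that a site on a miRNA-sized feature (≤ 30 nt) is
    placed on the first (5′) nucleotide when that nucleotide is a U,
    mirroring the observed 5′-U preference. With
    ``rrna_known_stoich`` set, every designated known site of the rRNA
    locus is additionally modified at that stoichiometry.
    """
    if (frac_modified_features is None) == (n_modified is None):
        raise ConfigError("specify exactly one of frac_modified_features / n_modified")
    lo, hi = stoich_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ConfigError("stoichiometry range must lie in (0, 1]")
    rng = substream(seed, "psi_sites")
    eligible = [f for f in ref.features if f.cls in classes]
    if n_modified is not None:
        # exact-count mode guarantees n_modified features; U-less features
        # cannot carry a site, so they are not eligible
        eligible = [f for f in eligible if "T" in ref.feature_seq(f)]
        if n_modified > len(eligible):
            raise ConfigError("n_modified exceeds the number of eligible features")
        chosen = [eligible[i] for i in sorted(rng.choice(len(eligible), n_modified, replace=False))]
    else:
        if not (0.0 <= frac_modified_features <= 1.0):
            raise ConfigError("frac_modified_features must lie in [0, 1]")
        chosen = [f for f in eligible if rng.random() < frac_modified_features]

    sites: dict[tuple[str, int], float] = {}
    for f in chosen:
        seq = ref.feature_seq(f)
        u_offsets = [i for i, b in enumerate(seq) if b == "T"]
        if not u_offsets:
            logger.warning("feature %s contains no U; skipped", f.id)
            continue
        picked: list[int] = []
        n_sites = min(sites_per_feature, len(u_offsets))
        for k in range(n_sites):
            pool = [o for o in u_offsets if o not in picked]
            if not pool:
                break
            if (k == 0 and five_prime_bias > 0 and f.length <= 30
                    and seq[0] == "T" and rng.random() < five_prime_bias):
                off = 0
            else:
                off = int(pool[rng.integers(0, len(pool))])
            picked.append(off)
        for off in picked:
            pos = f.start + off if f.strand == "+" else f.end - 1 - off
            sites[(f.contig, pos)] = float(rng.uniform(lo, hi))

    if rrna_known_stoich is not None:
        for contig, pos in ref.known_rrna_sites:
            sites[(contig, pos)] = float(rrna_known_stoich)

    truth = PsiGroundTruth(sites)
    truth.validate(ref)
    return truth


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

ASSAYS = ("input", "ip_bound", "ip_unbound", "cmc_plus", "cmc_mock", "mn_plus", "mn_mock")


@dataclass
class SimConfig:
    """Study-condition parameters for the molecule-level simulator.

    Probabilities are per molecule/base as documented on each field;
    fragment windows emulate the 15–35-nt size selection of small RNA
    libraries (miRNAs are emitted full length, longer loci shed
    fragments; tRNAs shed end-biased fragments, i.e. tRFs).
    """

    master_seed: int = 0
    molecules_per_library: int = 50_000
    expression_sigma: float = 1.0      # log-normal sd of per-feature molecule share
    rrna_share: float = 0.15           # fixed share of molecules from the rRNA locus
    ip_capture_eff: float = 0.8        # per-Ψ antibody capture probability
    ip_background: float = 0.05        # capture probability for Ψ-free molecules
    adduct_prob: float = 0.9           # CMC adduct formation probability per Ψ
    p_del: float = 0.3                 # per-adduct 1-nt deletion probability (Mn²⁺ RT)
    p_mis: float = 0.3                 # per-adduct mismatch probability (Mn²⁺ RT)
    seq_error: float = 0.001           # per-base miscall rate
    len_jitter: float = 0.1            # probability a miRNA molecule is 3′-trimmed by 1 nt
    frag_len_range: tuple[int, int] = (18, 28)
    n_ip_pairs: int = 3
    n_cmc_pairs: int = 3
    n_mn_pairs: int = 3
    assays: tuple[str, ...] = ("ip", "cmc", "mn")
    emit_input: bool = False
    raw_mode: bool = False             # append 3′ adapter (+ random ends) to reads
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    random_ends: int = 0
    # metadata only: the order of adapter ligation vs CMC treatment does not
    # change the simulated output and is recorded for provenance
    protocol_order: str = "ligation_first"

    def validate(self) -> None:
        for name in ("ip_capture_eff", "ip_background", "adduct_prob",
                     "p_del", "p_mis", "seq_error", "len_jitter", "rrna_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.p_del + self.p_mis > 1.0:
            raise ConfigError("p_del + p_mis must be <= 1")
        if self.molecules_per_library <= 0:
            raise ConfigError("molecules_per_library must be > 0")
        if self.frag_len_range[0] < 15 or self.frag_len_range[0] > self.frag_len_range[1]:
            raise ConfigError("invalid fragment length range")
        unknown = set(self.assays) - {"ip", "cmc", "mn"}
        if unknown:
            raise ConfigError(f"unknown assays: {sorted(unknown)}")


@dataclass
class SimulatedLibrary:
    """One sequencing library: reads plus pairing metadata."""

    label: str
    assay: str
    replicate: int
    pair: str
    reads: list[tuple[str, str, str]]  # (id, sequence, quality)
    insert_truth: list[str] | None = None  # raw mode: post-error insert per read

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class SimResult:
    libraries: list[SimulatedLibrary]
    feature_counts: pd.DataFrame    # features × libraries, molecule counts pre-error
    edit_truth: pd.DataFrame        # injected Mn²⁺ edits: library, contig, pos, n_del, n_mis
    site_table: pd.DataFrame        # the ground-truth Ψ sites with feature offsets
    species_table: pd.DataFrame     # emitted species: feature, offset, length, sequence, weight, n_sites
    manifest: dict

    def library(self, label: str) -> SimulatedLibrary:
        for lib in self.libraries:
            if lib.label == label:
                return lib
        raise KeyError(label)


@dataclass
class _FeatInfo:
    feature: Feature
    seq: str
    site_offsets: list[int]
    site_stoich: list[float]
    # discrete small RNA species (offset, length, weight); None → window cloud
    species: list[tuple[int, int, float]] | None = None

    def site_refpos(self, off: int) -> int:
        f = self.feature
        return f.start + off if f.strand == "+" else f.end - 1 - off


def _prepare_features(ref: ToyReference, truth: PsiGroundTruth) -> list[_FeatInfo]:
    truth.validate(ref)
    infos = []
    for f in ref.features:
        seq = ref.feature_seq(f)
        offs, stoi = [], []
        for (contig, pos), s in truth.sites.items():
            if contig == f.contig and f.start <= pos < f.end:
                off = pos - f.start if f.strand == "+" else f.end - 1 - pos
                offs.append(off)
                stoi.append(s)
        order = np.argsort(offs)
        infos.append(_FeatInfo(f, seq, [offs[i] for i in order], [stoi[i] for i in order]))
    return infos


def _species_layouts(rng: np.random.Generator, infos: list[_FeatInfo],
                     cfg: "SimConfig") -> None:
    """Assign each feature its emitted small RNA species.

    miRNA-sized features emit the full-length product (with optional
    1-nt 3′ trimming handled at sampling time). Longer TE/tRNA/other
    loci emit a phased tiling of discrete species (Dicer-product-like:
    ~21-nt register, lengths 21–24, the last species anchored at the
    3′ end so tRNAs shed a CCA-ending 3′ tRF), with Dirichlet-weighted
    relative abundances fixed across libraries. The rRNA locus keeps a
    uniform degradation-fragment cloud (species = None).
    """
    step = 21
    for info in infos:
        cls = info.feature.cls
        L = len(info.seq)
        if cls == "rRNA":
            info.species = None
            continue
        if cls == "miRNA" or L <= cfg.frag_len_range[1]:
            info.species = [(0, L, 1.0)]
            continue
        lens_pool = (21, 22, 23, 24)
        offs = list(range(0, max(L - max(lens_pool), 0) + 1, step))
        anchor = L - int(lens_pool[rng.integers(0, len(lens_pool))])
        species: list[tuple[int, int]] = []
        for o in offs:
            ln = int(lens_pool[rng.integers(0, len(lens_pool))])
            if o + ln > L:
                ln = L - o
            species.append((o, ln))
        if species[-1][0] != anchor:
            species.append((anchor, L - anchor))
        w = rng.dirichlet(np.full(len(species), 2.0))
        info.species = [(o, ln, float(wi)) for (o, ln), wi in zip(species, w)]


def _expression_shares(rng: np.random.Generator, infos: list[_FeatInfo],
                       sigma: float, rrna_share: float) -> np.ndarray:
    w = np.exp(rng.normal(0.0, sigma, size=len(infos)))
    is_rrna = np.array([fi.feature.cls == "rRNA" for fi in infos])
    shares = np.zeros(len(infos))
    if is_rrna.any():
        shares[is_rrna] = rrna_share * w[is_rrna] / w[is_rrna].sum()
        if (~is_rrna).any():
            shares[~is_rrna] = (1 - rrna_share) * w[~is_rrna] / w[~is_rrna].sum()
    else:
        shares = w / w.sum()
    return shares


def _sample_fragments(rng: np.random.Generator, infos: list[_FeatInfo],
                      shares: np.ndarray, n: int, cfg: SimConfig
                      ) -> list[tuple[int, int, int, int]]:
    """Sample molecule windows; returns grouped (feature_idx, offset, length, count)."""
    counts = rng.multinomial(n, shares)
    lo, hi = cfg.frag_len_range
    groups: list[tuple[int, int, int, int]] = []
    for fi, c in enumerate(counts):
        if c == 0:
            continue
        info = infos[fi]
        L = len(info.seq)
        if info.species is not None:
            if len(info.species) == 1:
                off, ln, _ = info.species[0]
                nj = rng.binomial(c, cfg.len_jitter) if ln - 1 >= 15 else 0
                if c - nj:
                    groups.append((fi, off, ln, int(c - nj)))
                if nj:
                    groups.append((fi, off, ln - 1, int(nj)))
            else:
                w = np.array([s[2] for s in info.species])
                alloc = rng.multinomial(c, w / w.sum())
                for (off, ln, _), k in zip(info.species, alloc):
                    if k:
                        groups.append((fi, off, ln, int(k)))
            continue
        # degradation cloud (rRNA): uniform windows
        lens = rng.integers(lo, min(hi, L) + 1, size=c)
        offs = (rng.random(c) * (L - lens + 1)).astype(int)
        code = offs.astype(np.int64) * 1000 + lens
        uniq, cnt = np.unique(code, return_counts=True)
        for u, k in zip(uniq, cnt):
            groups.append((fi, int(u // 1000), int(u % 1000), int(k)))
    return groups


def _psi_configs(rng: np.random.Generator, info: _FeatInfo, off: int, ln: int,
                 count: int) -> list[tuple[tuple[int, ...], tuple[float, ...], int]]:
    """Split a fragment group into Ψ-occupancy configurations.

    Returns (covered site offsets carrying Ψ, their stoichiometries, count);
    a multinomial over the 2^k occupancy patterns of the k covered sites —
    the exact count-level equivalent of per-molecule Bernoulli draws.
    """
    cov = [(o, s) for o, s in zip(info.site_offsets, info.site_stoich) if off <= o < off + ln]
    if not cov:
        return [((), (), count)]
    k = len(cov)
    probs = np.ones(2 ** k)
    for j, (_, s) in enumerate(cov):
        bit = (np.arange(2 ** k) >> j) & 1
        probs *= np.where(bit == 1, s, 1.0 - s)
    alloc = rng.multinomial(count, probs)
    out = []
    for mask, c in enumerate(alloc):
        if c == 0:
            continue
        offs = tuple(cov[j][0] for j in range(k) if (mask >> j) & 1)
        stoi = tuple(cov[j][1] for j in range(k) if (mask >> j) & 1)
        out.append((offs, stoi, int(c)))
    return out


_MIS_ALTS = {b: [x for x in BASES if x != b] for b in BASES}


def _build_variant(info: _FeatInfo, off: int, ln: int,
                   edits: tuple[tuple[int, str, str], ...]) -> str:
    """Apply (site_offset, kind, alt_base) edits to the sense fragment."""
    frag = list(info.seq[off:off + ln])
    for so, kind, alt in sorted(edits, key=lambda e: -e[0]):
        i = so - off
        if kind == "mis":
            frag[i] = alt
        else:
            del frag[i]
    return "".join(frag)


class _LibraryBuilder:
    """Accumulates (sequence, count) groups and emits error-injected reads."""

    def __init__(self, label: str, assay: str, replicate: int, pair: str, cfg: SimConfig):
        self.label = label
        self.assay = assay
        self.replicate = replicate
        self.pair = pair
        self.cfg = cfg
        self.groups: list[tuple[str, int]] = []
        self.feature_counts: dict[int, int] = {}
        self.edits: dict[tuple[str, int], list[int]] = {}  # refpos → [n_del, n_mis]

    def add(self, fi: int, seq: str, count: int,
            ref_edits: Iterable[tuple[str, int, str]] = ()) -> None:
        if count <= 0:
            return
        self.groups.append((seq, count))
        self.feature_counts[fi] = self.feature_counts.get(fi, 0) + count
        for contig, pos, kind in ref_edits:
            rec = self.edits.setdefault((contig, pos), [0, 0])
            rec[0 if kind == "del" else 1] += count

    def emit(self, rng: np.random.Generator) -> SimulatedLibrary:
        cfg = self.cfg
        reads: list[tuple[str, str, str]] = []
        inserts: list[str] | None = [] if cfg.raw_mode else None
        hiq: dict[int, str] = {}
        i = 0
        for seq, count in self.groups:
            if cfg.raw_mode:
                for _ in range(count):
                    e5 = _random_seq(rng, cfg.random_ends)
                    e3 = _random_seq(rng, cfg.random_ends)
                    raw = e5 + seq + e3 + cfg.adapter
                    chars = list(raw)
                    nerr = rng.binomial(len(chars), cfg.seq_error)
                    qual = list(hiq.setdefault(len(chars), HIGH_Q_CHAR * len(chars)))
                    if nerr:
                        for p in rng.choice(len(chars), size=nerr, replace=False):
                            chars[p] = _MIS_ALTS[chars[p]][rng.integers(0, 3)]
                            qual[p] = LOW_Q_CHAR
                    read = "".join(chars)
                    reads.append((f"{self.label}.{i}", read, "".join(qual)))
                    inserts.append(read[cfg.random_ends:cfg.random_ends + len(seq)])
                    i += 1
            else:
                L = len(seq)
                q = hiq.setdefault(L, HIGH_Q_CHAR * L)
                nerr = rng.binomial(L, cfg.seq_error, size=count)
                nclean = int((nerr == 0).sum())
                for _ in range(nclean):
                    reads.append((f"{self.label}.{i}", seq, q))
                    i += 1
                for k in nerr[nerr > 0]:
                    chars = list(seq)
                    qual = list(q)
                    for p in rng.choice(L, size=int(k), replace=False):
                        chars[p] = _MIS_ALTS[chars[p]][rng.integers(0, 3)]
                        qual[p] = LOW_Q_CHAR
                    reads.append((f"{self.label}.{i}", "".join(chars), "".join(qual)))
                    i += 1
        return SimulatedLibrary(self.label, self.assay, self.replicate, self.pair,
                                reads, inserts)


def simulate_libraries(ref: ToyReference, truth: PsiGroundTruth,
                       cfg: SimConfig) -> SimResult:
    """Simulate all configured library conditions at the molecule level.

    Per library, ``molecules_per_library`` molecules are drawn from
    features in proportion to a fixed log-normal expression profile;
    each Ψ site is occupied per molecule at its stoichiometry; the
    assay chemistry (capture, adduct dropout, or Mn²⁺ read-through
    edits) is applied; finally a uniform per-base miscall rate corrupts
    the emitted reads. IP bound + unbound molecule counts equal the
    input count exactly for every replicate.
    """
    cfg.validate()
    ref.validate()
    infos = _prepare_features(ref, truth)
    _species_layouts(substream(cfg.master_seed, "species"), infos, cfg)
    shares = _expression_shares(substream(cfg.master_seed, "expression"),
                                infos, cfg.expression_sigma, cfg.rrna_share)
    n = cfg.molecules_per_library
    builders: list[_LibraryBuilder] = []

    def new_builder(assay: str, rep: int, pair: str) -> _LibraryBuilder:
        b = _LibraryBuilder(f"{assay}_r{rep}", assay, rep, pair, cfg)
        builders.append(b)
        return b

    if "ip" in cfg.assays:
        eff, bg = cfg.ip_capture_eff, cfg.ip_background
        for r in range(1, cfg.n_ip_pairs + 1):
            rng = substream(cfg.master_seed, f"ip{r}")
            pair = f"ip_r{r}"
            b_in = new_builder("input", r, pair) if cfg.emit_input else None
            b_b = new_builder("ip_bound", r, pair)
            b_u = new_builder("ip_unbound", r, pair)
            for fi, off, ln, c in _sample_fragments(rng, infos, shares, n, cfg):
                info = infos[fi]
                for psi_offs, _stoi, k in _psi_configs(rng, info, off, ln, c):
                    m = len(psi_offs)
                    p = bg if m == 0 else 1.0 - (1.0 - eff) ** m
                    nb = int(rng.binomial(k, p))
                    seq = info.seq[off:off + ln]
                    if b_in is not None:
                        b_in.add(fi, seq, k)
                    b_b.add(fi, seq, nb)
                    b_u.add(fi, seq, k - nb)

    if "cmc" in cfg.assays:
        a = cfg.adduct_prob
        for r in range(1, cfg.n_cmc_pairs + 1):
            rng = substream(cfg.master_seed, f"cmc{r}")
            pair = f"cmc_r{r}"
            b_m = new_builder("cmc_mock", r, pair)
            b_p = new_builder("cmc_plus", r, pair)
            for fi, off, ln, c in _sample_fragments(rng, infos, shares, n, cfg):
                b_m.add(fi, infos[fi].seq[off:off + ln], c)
            for fi, off, ln, c in _sample_fragments(rng, infos, shares, n, cfg):
                info = infos[fi]
                for psi_offs, _stoi, k in _psi_configs(rng, info, off, ln, c):
                    # a molecule survives standard RT iff no site is adducted
                    surv = int(rng.binomial(k, (1.0 - a) ** len(psi_offs)))
                    b_p.add(fi, info.seq[off:off + ln], surv)

    if "mn" in cfg.assays:
        a, pd_, pm = cfg.adduct_prob, cfg.p_del, cfg.p_mis
        for r in range(1, cfg.n_mn_pairs + 1):
            rng = substream(cfg.master_seed, f"mn{r}")
            pair = f"mn_r{r}"
            b_m = new_builder("mn_mock", r, pair)
            b_p = new_builder("mn_plus", r, pair)
            for fi, off, ln, c in _sample_fragments(rng, infos, shares, n, cfg):
                b_m.add(fi, infos[fi].seq[off:off + ln], c)
            for fi, off, ln, c in _sample_fragments(rng, infos, shares, n, cfg):
                info = infos[fi]
                f = info.feature
                for psi_offs, _stoi, k in _psi_configs(rng, info, off, ln, c):
                    if not psi_offs:
                        b_p.add(fi, info.seq[off:off + ln], k)
                        continue
                    # per-Ψ outcomes under Mn²⁺ RT: clean read-through,
                    # 1-nt deletion, or one of three non-cognate bases
                    per_site: list[list[tuple[str, str, float]]] = []
                    for so in psi_offs:
                        alts = _MIS_ALTS[info.seq[so]]
                        per_site.append(
                            [("none", "", (1 - a) + a * (1 - pd_ - pm)),
                             ("del", "", a * pd_)]
                            + [("mis", alt, a * pm / 3.0) for alt in alts])
                    combos = list(itertools.product(*per_site))
                    probs = np.array([np.prod([o[2] for o in cb]) for cb in combos])
                    alloc = rng.multinomial(k, probs)
                    for cb, kc in zip(combos, alloc):
                        if kc == 0:
                            continue
                        edits = tuple((so, o[0], o[1]) for so, o in zip(psi_offs, cb)
                                      if o[0] != "none")
                        seq = _build_variant(info, off, ln, edits)
                        ref_edits = [(f.contig, info.site_refpos(so), kind)
                                     for so, kind, _ in edits]
                        b_p.add(fi, seq, int(kc), ref_edits)

    # emit reads with per-base miscalls
    libraries = []
    for b in builders:
        rng = substream(cfg.master_seed, f"errors:{b.label}")
        libraries.append(b.emit(rng))

    fc = pd.DataFrame(
        {b.label: [b.feature_counts.get(i, 0) for i in range(len(infos))] for b in builders},
        index=[fi.feature.id for fi in infos],
    )
    edit_rows = []
    for b in builders:
        for (contig, pos), (nd, nm) in sorted(b.edits.items()):
            edit_rows.append((b.label, contig, pos, nd, nm))
    edit_truth = pd.DataFrame(edit_rows, columns=["library", "contig", "pos", "n_del", "n_mis"])
    species_rows = []
    for info in infos:
        if info.species is None:
            continue
        emitted = []
        for off, ln, w in info.species:
            if len(info.species) == 1 and cfg.len_jitter > 0 and ln - 1 >= 15:
                emitted.append((off, ln, w * (1 - cfg.len_jitter)))
                emitted.append((off, ln - 1, w * cfg.len_jitter))
            else:
                emitted.append((off, ln, w))
        for off, ln, w in emitted:
            n_sites = sum(1 for o in info.site_offsets if off <= o < off + ln)
            species_rows.append((info.feature.id, off, ln, info.seq[off:off + ln],
                                 w, n_sites))
    species_table = pd.DataFrame(species_rows, columns=[
        "feature", "offset", "length", "sequence", "weight", "n_sites"])
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "n_features": len(infos),
        "n_sites": len(truth),
        "libraries": [{"label": l.label, "assay": l.assay, "replicate": l.replicate,
                       "pair": l.pair, "n_reads": len(l)} for l in libraries],
    }
    return SimResult(libraries, fc, edit_truth, truth.to_frame(ref),
                     species_table, manifest)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_fastq(lib: SimulatedLibrary, path: str | Path, gzip_out: bool = False) -> None:
    opener = gzip.open if gzip_out else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in lib.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_tables(result: SimResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.site_table.to_csv(outdir / "psi_sites.tsv", sep="\t", index=False)
    result.feature_counts.rename_axis("feature").to_csv(
        outdir / "feature_molecule_counts.tsv", sep="\t")
    result.edit_truth.to_csv(outdir / "mn_edit_truth.tsv", sep="\t", index=False)


def write_manifest(result: SimResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
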