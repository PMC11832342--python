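"""End-to-end orchestration: simulate → preprocess → align → enrich →
sitecall → aggregate, plus the package's canned study designs.

A single :class:`RunConfig` (optionally expanded from a preset) drives
every stage; all randomness flows from the master seed, so identical
configurations reproduce byte-identical result tables. The experiment
helpers at the bottom (`run_ip_cmc_experiment`, `run_mn_experiment`,
`cmc_depletion_ratio`, `run_rrna_experiment`) run the same stages
in memory and are what the acceptance script and the recovery tests
call.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import enrich as en
from . import reads_io as rio
from . import sitecall as sc
from . import aggregate as ag
from . import simdata as sd

logger = logging.getLogger("psifinder.pipeline")

#: Branch-specific preprocessing/alignment parameter sets.
PRESETS: dict[str, dict] = {
    "toy": dict(min_len=15, max_len=30, min_q=None, max_mismatch=1),
    "plant_flower": dict(min_len=20, max_len=25, min_q=None, max_mismatch=1),
    "plant_pollen": dict(min_len=18, max_len=30, min_q=None, max_mismatch=0),
    "mouse_testis": dict(min_len=14, max_len=44, min_q=20, q_frac=0.9,
                         max_mismatch=3, adapter="AGATCGGAAGAGCACACGTCTGAAC"),
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; presets fill the branch knobs."""

    preset: str = "toy"
    master_seed: int = 0
    ref_spec: sd.ReferenceSpec = field(default_factory=sd.ReferenceSpec)
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    n_modified: int = 30
    stoich_range: tuple[float, float] = (0.5, 1.0)
    five_prime_bias: float = 0.5
    rrna_known_stoich: float | None = 0.8
    # preprocessing
    min_len: int = 15
    max_len: int = 30
    min_q: int | None = None
    q_frac: float = 0.9
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    # alignment
    max_mismatch: int = 1
    # enrichment
    min_mean: float = 10.0
    alpha: float = 0.01
    # site calling
    min_reads: int = sc.DEFAULT_MIN_READS
    min_fold: float = sc.DEFAULT_MIN_FOLD
    min_mock_cov: int = sc.DEFAULT_MIN_READS
    gzip_fastq: bool = False

    @classmethod
    def from_preset(cls, preset: str = "toy", master_seed: int = 0, **overrides) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        cfg = cls(preset=preset, master_seed=master_seed, **PRESETS[preset])
        cfg = replace(cfg, **overrides)
        cfg.sim = replace(cfg.sim, master_seed=master_seed)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(data), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["ref_spec"] = _ref_spec_from(data.get("ref_spec", {}))
        sim = data.get("sim", {})
        for key in ("frag_len_range", "assays"):
            if key in sim:
                sim[key] = tuple(sim[key])
        data["sim"] = sd.SimConfig(**sim)
        for key in ("stoich_range",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _ref_spec_from(d: dict) -> sd.ReferenceSpec:
    kw = dict(d)
    for key in ("mirna", "te", "trna", "other"):
        if key in kw and isinstance(kw[key], dict):
            kw[key] = sd.ClassSpec(**kw[key])
    if "spacer_range" in kw:
        kw["spacer_range"] = tuple(kw["spacer_range"])
    return sd.ReferenceSpec(**kw)


# ---------------------------------------------------------------------------
# Stage helpers (shared by run_pipeline and the in-memory experiments)
# ---------------------------------------------------------------------------

def library_records(lib: sd.SimulatedLibrary) -> list[rio.ReadRecord]:
    return [rio.ReadRecord(rid, seq, qual, lib.label) for rid, seq, qual in lib.reads]


def simulate(cfg: RunConfig):
    ref = sd.build_toy_reference(cfg.ref_spec, seed=cfg.master_seed)
    truth = sd.assign_psi_sites(
        ref, n_modified=cfg.n_modified, stoich_range=cfg.stoich_range,
        five_prime_bias=cfg.five_prime_bias, seed=cfg.master_seed,
        rrna_known_stoich=cfg.rrna_known_stoich)
    sim = sd.simulate_libraries(ref, truth, cfg.sim)
    return ref, truth, sim


def preprocess(libraries: Sequence[sd.SimulatedLibrary], cfg: RunConfig):
    """Trim (raw mode), filter and collapse every library.

    Returns (collapsed records across libraries, per-library masked
    groups for the Mn²⁺ branch, per-library stage logs).
    """
    all_reads: list[rio.ReadRecord] = []
    mn_reads: list[rio.ReadRecord] = []
    logs: dict[str, list[rio.StageLog]] = {}
    for lib in libraries:
        reads = library_records(lib)
        stage_logs = []
        if cfg.sim.raw_mode:
            reads, tlog = rio.trim_adapter(reads, cfg.sim.adapter,
                                           random_ends=cfg.sim.random_ends)
            stage_logs.append(tlog)
        reads, flog = rio.filter_reads(reads, cfg.min_len, cfg.max_len,
                                       cfg.min_q, cfg.q_frac)
        stage_logs.append(flog)
        logs[lib.label] = stage_logs
        all_reads.extend(reads)
        if lib.assay.startswith("mn_"):
            mn_reads.extend(reads)
    collapsed = rio.collapse_reads(all_reads)
    masked = rio.collapse_with_masks(mn_reads) if mn_reads else {}
    return collapsed, masked, logs


def enrichment_for_contrast(
    collapsed: Sequence[rio.CollapsedRead],
    meta: pd.DataFrame,
    annot: pd.DataFrame,
    contrast: tuple[str, str],
    min_mean: float = 10.0,
    aggregate_by: str | None = "features",
    paired: bool = False,
) -> pd.DataFrame:
    """Count matrix restricted to the contrast's libraries, then
    size factors → dispersion → Wald test."""
    libs = [l for l in meta.index if meta.loc[l, "condition"] in contrast]
    sub_meta = meta.loc[libs]
    sub = [rio.CollapsedRead(c.sequence, {k: v for k, v in c.counts.items() if k in libs})
           for c in collapsed]
    sub = [c for c in sub if c.counts]
    cm = en.build_count_matrix(sub, sub_meta, min_mean=min_mean, annot=annot,
                               aggregate_by=aggregate_by)
    sf = en.compute_size_factors(cm.counts)
    disp = en.estimate_dispersion(cm.counts, sf, sub_meta["condition"])
    return en.test_enrichment(cm, sf, disp, contrast, paired=paired)


def mn_site_calls(
    masked: Mapping[str, Sequence[rio.MaskedGroup]],
    ref: sd.ToyReference,
    cfg: RunConfig,
    aln_cache: dict[str, list[al.Alignment]] | None = None,
):
    """Pool Mn²⁺ replicates per condition, build pileups, call sites."""
    index = al.RefIndex(ref)
    seqs = sorted({g.sequence for groups in masked.values() for g in groups})
    # unique placements only: multimapped reads would transfer family
    # divergence positions into the pileup as spurious mismatches
    cache = aln_cache if aln_cache is not None else {}
    for s in seqs:
        if s not in cache:
            cache[s] = al.align_with_deletions([s], index, cfg.max_mismatch,
                                               policy="unique_only")
    profiles = {}
    for lib, groups in masked.items():
        triples = [(cache[g.sequence][0], g.count, g.lowq)
                   for g in groups if cache.get(g.sequence)]
        profiles[lib] = sc.build_pileup(triples, ref)
    pooled = {}
    for cond in ("mn_plus", "mn_mock"):
        libs = sorted(l for l in profiles if l.startswith(cond))
        prof = sc.PileupProfile()
        for l in libs:
            prof = prof.add(profiles[l])
        pooled[cond] = prof
    calls = sc.call_psi_sites(pooled["mn_plus"], pooled["mn_mock"],
                              cfg.min_reads, cfg.min_fold, cfg.min_mock_cov)
    return calls, pooled, profiles


def recovery_metrics(truth_features: set[str], results: pd.DataFrame,
                     direction: int, alpha: float = 0.05) -> dict:
    """Sensitivity and empirical FDR of one feature-level test against truth."""
    sig = results[(results.padj < alpha) & (np.sign(results.log2FC) == direction)]
    flagged = set(sig.index)
    tp = flagged & truth_features
    tested_truth = truth_features & set(results.index)
    return {
        "n_flagged": len(flagged),
        "n_true": len(truth_features),
        "sensitivity": len(tp) / len(truth_features) if truth_features else float("nan"),
        "fdr": (len(flagged - truth_features) / len(flagged)) if flagged else 0.0,
        "n_true_tested": len(tested_truth),
    }


def species_recovery_metrics(sim: sd.SimResult, results: pd.DataFrame,
                             direction: int, alpha: float = 0.05) -> dict:
    """Recovery of modified features from a per-sequence enrichment test.

    The unit of testing is the unique sequence (as in the per-sequence
    DESeq2-style analysis); a Ψ-modified feature counts as recovered
    when at least one of its emitted Ψ-bearing species is flagged with
    the expected sign. The empirical FDR is the fraction of flagged
    sequences that carry no Ψ site.
    """
    sp = sim.species_table
    truth_seqs = set(sp[sp.n_sites > 0].sequence)
    modified = set(sim.site_table.feature) - {""}
    sig = results[(results.padj < alpha) & (np.sign(results.log2FC) == direction)]
    flagged = set(sig.index)
    by_feature = sp[sp.n_sites > 0].groupby("feature")["sequence"].apply(set)
    detected = {f for f in modified
                if f in by_feature.index and by_feature[f] & flagged}
    return {
        "n_flagged": len(flagged),
        "n_true": len(modified),
        "n_detected": len(detected),
        "sensitivity": len(detected) / len(modified) if modified else float("nan"),
        "fdr": (len(flagged - truth_seqs) / len(flagged)) if flagged else 0.0,
    }


# ---------------------------------------------------------------------------
# Full pipeline with file outputs
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, writing tables, manifest and report under ``outdir``."""
    out = Path(outdir)
    for sub in ("reference", "fastq", "collapsed", "enrich", "sitecall", "aggregate"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {"preset": cfg.preset, "master_seed": cfg.master_seed, "stages": []}

    ref, truth, sim = simulate(cfg)
    ref.write_fasta(out / "reference" / "genome.fa")
    ref.write_bed(out / "reference" / "features.bed")
    sd.write_truth_tables(sim, out / "reference")
    for lib in sim.libraries:
        suffix = ".fastq.gz" if cfg.gzip_fastq else ".fastq"
        sd.write_fastq(lib, out / "fastq" / f"{lib.label}{suffix}", cfg.gzip_fastq)
    manifest["stages"].append({"stage": "simulate", "n_libraries": len(sim.libraries),
                               "n_sites": int(len(truth))})

    # read back from disk so the I/O layer is part of every run
    libraries = []
    for lib in sim.libraries:
        suffix = ".fastq.gz" if cfg.gzip_fastq else ".fastq"
        recs = rio.read_fastq(out / "fastq" / f"{lib.label}{suffix}", lib.label)
        libraries.append(sd.SimulatedLibrary(lib.label, lib.assay, lib.replicate,
                                             lib.pair, [(r.id, r.sequence, r.quality)
                                                        for r in recs]))
    collapsed, masked, logs = preprocess(libraries, cfg)
    rio.write_count_table(collapsed, out / "collapsed" / "counts.tsv")
    manifest["stages"].append({
        "stage": "preprocess", "n_unique": len(collapsed),
        "discards": {lib: {l.stage: dict(l.discarded) for l in ls}
                     for lib, ls in sorted(logs.items())}})

    index = al.RefIndex(ref)
    alignments = al.align_reads(collapsed, index, cfg.max_mismatch, policy="all_best")
    annot = al.annotate_alignments(alignments, ref)
    al.write_alignment_table(alignments, out / "collapsed" / "alignments.tsv")
    manifest["stages"].append({"stage": "align", "n_aligned_seqs": int(annot.shape[0])})

    meta = en.metadata_from_sim(sim)
    results: dict[str, pd.DataFrame] = {}
    feat_results: dict[str, pd.DataFrame] = {}
    contrasts = {"ip": ("ip_bound", "ip_unbound"), "cmc": ("cmc_plus", "cmc_mock")}
    for name, contrast in contrasts.items():
        if not any(meta.condition == contrast[0]):
            continue
        # per-unique-sequence testing; locus assignment happens downstream
        res = enrichment_for_contrast(collapsed, meta, annot, contrast,
                                      cfg.min_mean, aggregate_by=None)
        res.to_csv(out / "enrich" / f"{name}_results.tsv", sep="\t",
                   float_format="%.6g")
        results[name] = res
        feat_results[name] = feature_rollup(res, annot)
        feat_results[name].to_csv(out / "enrich" / f"{name}_by_feature.tsv",
                                  sep="\t", float_format="%.6g")
    manifest["stages"].append({"stage": "enrich", "contrasts": sorted(results)})

    site_calls = mn_feats = None
    if masked:
        site_calls, pooled, _ = mn_site_calls(masked, ref, cfg)
        sc.write_site_table(site_calls, out / "sitecall" / "mn_site_calls.tsv")
        mn_feats = sc.per_feature_calls(site_calls, ref)
        mn_feats.to_csv(out / "sitecall" / "mn_feature_calls.tsv", sep="\t",
                        float_format="%.6g")
        meta_prof = sc.positional_metaprofile(site_calls, ref)
        meta_prof.to_csv(out / "sitecall" / "positional_metaprofile.tsv",
                         sep="\t", index=False, float_format="%.6g")

    consensus = venn = None
    if "ip" in feat_results and "cmc" in feat_results and mn_feats is not None:
        consensus, venn = sc.consensus_calls(feat_results["ip"], feat_results["cmc"],
                                             mn_feats, alpha=cfg.alpha)
        consensus.to_csv(out / "sitecall" / "consensus.tsv", sep="\t")
        with open(out / "sitecall" / "venn.json", "w") as fh:
            json.dump(venn, fh, sort_keys=True, indent=1)

    if ref.known_rrna_sites and "cmc" in results:
        site_means, track = _rrna_validation(collapsed, alignments, ref, meta)
        site_means.rename_axis("site").to_csv(out / "sitecall" / "rrna_site_log2fc.tsv",
                                              sep="\t", float_format="%.6g")
        sc.write_bedgraph(track, out / "sitecall" / "rrna_track.bedgraph")

    _aggregate_outputs(out, collapsed, annot, results, consensus, ref, alignments,
                       meta, cfg)

    report = {"venn": venn, "recovery": {}}
    truth_feats = set(sim.site_table.feature) - {""}
    if "ip" in results:
        report["recovery"]["ip"] = species_recovery_metrics(sim, results["ip"], +1)
    if "cmc" in results:
        report["recovery"]["cmc"] = species_recovery_metrics(sim, results["cmc"], -1)
    if mn_feats is not None and len(mn_feats):
        called = set(mn_feats[mn_feats.called].index)
        report["recovery"]["mn"] = {
            "n_called_features": len(called),
            "sensitivity": (len(called & truth_feats) / len(truth_feats)
                            if truth_feats else float("nan")),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)
    return {"ref": ref, "truth": truth, "sim": sim, "collapsed": collapsed,
            "annot": annot, "results": results, "site_calls": site_calls,
            "mn_feature_calls": mn_feats, "consensus": consensus, "venn": venn,
            "report": report}


def _rrna_validation(collapsed, alignments, ref, meta, window: int = 2):
    rrna = next(f for f in ref.features if f.cls == "rRNA")
    interval = (rrna.contig, rrna.start, rrna.end)
    cmc_libs = [l for l in meta.index if meta.loc[l, "condition"] in ("cmc_plus", "cmc_mock")]
    counts_by_lib = {l: {} for l in cmc_libs}
    for c in collapsed:
        for l, n in c.counts.items():
            if l in counts_by_lib:
                counts_by_lib[l][c.sequence] = n
    tracks = {l: sc.coverage_track(alignments, counts_by_lib[l], interval)
              for l in cmc_libs}
    pairs = sorted(
        (l, l.replace("cmc_plus", "cmc_mock"))
        for l in cmc_libs if l.startswith("cmc_plus"))
    return sc.rrna_site_validation(tracks, interval, ref.known_rrna_sites, pairs, window)


def feature_rollup(results: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Per-feature view of a per-sequence enrichment table: each feature
    is represented by its most significant annotated sequence."""
    rows: dict[str, pd.Series] = {}
    for seq in results.index:
        if seq not in annot.index:
            continue
        for fid in str(annot.loc[seq, "features"]).split(","):
            if not fid:
                continue
            if fid not in rows or results.loc[seq, "padj"] < rows[fid]["padj"]:
                rec = results.loc[seq].copy()
                rec["sequence"] = seq
                rows[fid] = rec
    if not rows:
        return pd.DataFrame(columns=list(results.columns) + ["sequence"])
    table = pd.DataFrame(rows).T.sort_index()
    table.index.name = "feature"
    return table


def _aggregate_outputs(out, collapsed, annot, results, consensus, ref, alignments,
                       meta, cfg):
    if "cmc" in results:
        fam = ag.aggregate_family_enrichment(results["cmc"], annot)
        fam.to_csv(out / "aggregate" / "te_family_cmc.tsv", sep="\t", index=False,
                   float_format="%.6g")
        # metagene profile over the DME_target gene set, single-hit coverage
        genes = [f for f in ref.features if "DME_target" in f.gene_sets]
        if genes:
            uniq = al.align_reads(collapsed, al.RefIndex(ref), cfg.max_mismatch,
                                  policy="first_best")
            contig_lengths = {n: len(s) for n, s in ref.contigs.items()}
            cmc_libs = [l for l in meta.index
                        if meta.loc[l, "condition"] in ("cmc_plus", "cmc_mock")]
            cov = {}
            for lib in cmc_libs:
                counts = {c.sequence: c.counts.get(lib, 0) for c in collapsed}
                cov[lib] = ag.genome_coverage(uniq, counts, contig_lengths)
            prof = ag.metaplot_profile(
                cov, {l: meta.loc[l, "condition"] for l in cmc_libs}, genes,
                flank=150, window=25, smooth=6)
            prof.values.to_csv(out / "aggregate" / "dme_metaplot.tsv", sep="\t",
                               float_format="%.6g")
    if consensus is not None:
        psi = [s for s in consensus[consensus.high_confidence].index]
        psi_seqs, bg_seqs = [], []
        for c in collapsed:
            if c.sequence not in annot.index:
                continue
            feats = set(str(annot.loc[c.sequence, "features"]).split(","))
            (psi_seqs if feats & set(psi) else bg_seqs).append(c.sequence)
        comp = ag.terminal_nt_composition({"psi": psi_seqs, "background": bg_seqs},
                                          annot=annot)
        comp.to_csv(out / "aggregate" / "terminal_nt.tsv", sep="\t", index=False,
                    float_format="%.6g")
    trfs = ag.extract_trfs([a for a in alignments], ref)
    trfs.to_csv(out / "aggregate" / "trfs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Canned study designs (in-memory; used by tests and the acceptance script)
# ---------------------------------------------------------------------------

def run_ip_cmc_experiment(
    seed: int,
    null: bool = False,
    molecules: int = 50_000,
    n_pairs: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Parameter-recovery design: 200 toy features, 30 Ψ-modified at
    stoichiometry ≥ 0.5, Ψ-IP (capture 0.8, background 0.05) and CMC
    depletion (adduct 0.9), ``n_pairs`` replicate pairs. With
    ``null=True`` the truth is empty (no feature modified)."""
    cfg = RunConfig.from_preset("toy", master_seed=seed)
    cfg.sim = replace(cfg.sim, molecules_per_library=molecules,
                      n_ip_pairs=n_pairs, n_cmc_pairs=n_pairs, assays=("ip", "cmc"))
    ref = sd.build_toy_reference(cfg.ref_spec, seed=seed)
    if null:
        truth = sd.PsiGroundTruth({})
    else:
        truth = sd.assign_psi_sites(ref, n_modified=cfg.n_modified,
                                    stoich_range=cfg.stoich_range,
                                    five_prime_bias=cfg.five_prime_bias, seed=seed)
    sim = sd.simulate_libraries(ref, truth, cfg.sim)
    collapsed, _, _ = preprocess(sim.libraries, cfg)
    meta = en.metadata_from_sim(sim)
    # per-sequence testing, as in the per-sequence DESeq2-style analysis
    ip = enrichment_for_contrast(collapsed, meta, None, ("ip_bound", "ip_unbound"),
                                 cfg.min_mean, aggregate_by=None)
    cmc = enrichment_for_contrast(collapsed, meta, None, ("cmc_plus", "cmc_mock"),
                                  cfg.min_mean, aggregate_by=None)
    truth_feats = set(sim.site_table.feature) - {""}
    return {
        "ref": ref, "truth": truth, "sim": sim, "ip": ip, "cmc": cmc,
        "truth_features": truth_feats,
        "metrics": {
            "ip": species_recovery_metrics(sim, ip, +1, alpha),
            "cmc": species_recovery_metrics(sim, cmc, -1, alpha),
        },
        "pvalues": np.concatenate([ip.pvalue.to_numpy(), cmc.pvalue.to_numpy()]),
    }


def run_mn_experiment(
    seed: int,
    null: bool = False,
    molecules: int = 50_000,
    n_pairs: int = 3,
    stoich_range: tuple[float, float] = (0.3, 1.0),
    ref: sd.ToyReference | None = None,
    aln_cache: dict | None = None,
) -> dict:
    """Mn²⁺ site-recovery design (p_del = p_mis = 0.3, adduct 0.9).

    Reports per-truth-site recall within ±1 nt among sites with treated
    coverage ≥ 20, stratified by stoichiometry × adduct, plus the call
    count obtained with the treated/mock roles swapped (the mock
    direction must stay silent)."""
    cfg = RunConfig.from_preset("toy", master_seed=seed)
    cfg.sim = replace(cfg.sim, molecules_per_library=molecules,
                      n_mn_pairs=n_pairs, assays=("mn",))
    cfg = replace(cfg, stoich_range=stoich_range, rrna_known_stoich=None)
    if ref is None:
        ref = sd.build_toy_reference(cfg.ref_spec, seed=seed)
    if null:
        truth = sd.PsiGroundTruth({})
    else:
        truth = sd.assign_psi_sites(ref, n_modified=cfg.n_modified,
                                    stoich_range=cfg.stoich_range,
                                    five_prime_bias=cfg.five_prime_bias, seed=seed)
    sim = sd.simulate_libraries(ref, truth, cfg.sim)
    _, masked, _ = preprocess(sim.libraries, cfg)
    calls, pooled, _ = mn_site_calls(masked, ref, cfg, aln_cache=aln_cache)
    swapped = sc.call_psi_sites(pooled["mn_mock"], pooled["mn_plus"],
                                cfg.min_reads, cfg.min_fold, cfg.min_mock_cov)
    called_pos = {(r.contig, int(r.pos)) for _, r in calls[calls.called].iterrows()}
    a = cfg.sim.adduct_prob
    site_rows = []
    for (contig, pos), s in truth.sites.items():
        cov = pooled["mn_plus"].coverage.get((contig, pos), 0)
        hit = any((contig, pos + d) in called_pos for d in (-1, 0, 1))
        site_rows.append({"contig": contig, "pos": pos, "stoich": s,
                          "sa": s * a, "coverage": cov, "recovered": hit})
    sites = pd.DataFrame(site_rows, columns=["contig", "pos", "stoich", "sa",
                                             "coverage", "recovered"])
    strong = sites[(sites.sa >= 0.4) & (sites.coverage >= 20)]
    return {
        "ref": ref, "truth": truth, "calls": calls, "sites": sites,
        "n_calls": int(calls.called.sum()),
        "n_calls_swapped": int(swapped.called.sum()),
        "recall_strong": (float(strong.recovered.mean()) if len(strong)
                          else float("nan")),
        "n_strong": int(len(strong)),
    }


def cmc_depletion_ratio(seed: int, stoich: float, adduct: float,
                        molecules: int = 100_000) -> dict:
    """Observed CMC⁺/mock molecule ratio for a single-site feature vs the
    closed-form survival probability 1 − s·a, with its Monte-Carlo SE."""
    spec = sd.ReferenceSpec(
        mirna=sd.ClassSpec(8, 21, 23), te=sd.ClassSpec(0, 0, 0),
        trna=sd.ClassSpec(0, 0, 0), other=sd.ClassSpec(0, 0, 0), rrna_len=0)
    ref = sd.build_toy_reference(spec, seed=seed)
    target = next(f for f in ref.features if "T" in ref.feature_seq(f))
    seq = ref.feature_seq(target)
    off = seq.index("T")
    pos = target.start + off if target.strand == "+" else target.end - 1 - off
    truth = sd.PsiGroundTruth({(target.contig, pos): stoich})
    cfg = sd.SimConfig(master_seed=seed, molecules_per_library=molecules,
                       adduct_prob=adduct, assays=("cmc",), n_cmc_pairs=1,
                       len_jitter=0.0, seq_error=0.0, rrna_share=0.0,
                       expression_sigma=0.0)
    sim = sd.simulate_libraries(ref, truth, cfg)
    fc = sim.feature_counts
    n_plus = int(fc.loc[target.id, "cmc_plus_r1"])
    n_mock = int(fc.loc[target.id, "cmc_mock_r1"])
    p_surv = 1.0 - stoich * adduct
    share = n_mock / molecules  # plug-in estimate of the feature's share
    qx = share * p_surv
    # delta-method variance of X/Y for independent binomial counts
    var_ratio = (qx * (1 - qx) / (molecules * share ** 2)
                 + qx ** 2 * (1 - share) / (molecules * share ** 3))
    return {"observed": n_plus / n_mock if n_mock else float("nan"),
            "expected": p_surv, "mc_se": float(np.sqrt(var_ratio)),
            "n_mock": n_mock}


def run_rrna_experiment(seed: int, molecules: int = 50_000, n_pairs: int = 2,
                        sa: float = 0.8) -> dict:
    """Planted rRNA known sites at stoichiometry·adduct = ``sa``; paired
    CMC coverage log2 ratios across the locus; reports each site's rank
    quantile (lower = more depleted)."""
    cfg = RunConfig.from_preset("toy", master_seed=seed)
    adduct = cfg.sim.adduct_prob
    cfg = replace(cfg, n_modified=0, rrna_known_stoich=sa / adduct)
    cfg.sim = replace(cfg.sim, molecules_per_library=molecules,
                      n_cmc_pairs=n_pairs, assays=("cmc",))
    ref = sd.build_toy_reference(cfg.ref_spec, seed=seed)
    truth = sd.assign_psi_sites(ref, n_modified=0, seed=seed,
                                rrna_known_stoich=cfg.rrna_known_stoich)
    sim = sd.simulate_libraries(ref, truth, cfg.sim)
    collapsed, _, _ = preprocess(sim.libraries, cfg)
    index = al.RefIndex(ref)
    alignments = al.align_reads(collapsed, index, cfg.max_mismatch)
    meta = en.metadata_from_sim(sim)
    site_means, track = _rrna_validation(collapsed, alignments, ref, meta)
    values = track.log2fc.to_numpy()
    quantiles = {}
    for label, m in site_means.items():
        quantiles[label] = float((values < m).mean())
    rrna = next(f for f in ref.features if f.cls == "rRNA")
    cov_track = sc.coverage_track(
        alignments, {c.sequence: c.counts.get("cmc_mock_r1", 0) for c in collapsed},
        (rrna.contig, rrna.start, rrna.end))
    return {"site_means": site_means, "track": track, "quantiles": quantiles,
            "mean_mock_coverage": float(cov_track.mean())}
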