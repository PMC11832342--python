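# Methods

`psifinder` implements the computational side of a three-assay framework
for detecting pseudouridine (Ψ) in small RNAs, together with a
molecule-level read simulator that provides ground truth for every
stage. This note documents the models, the parameters that matter, the
numerical choices, and what the simulation does and does not capture.

## The three detection chemistries

Ψ is an isomer of uridine and is invisible to ordinary sequencing. The
framework exploits three orthogonal readouts:

1. **Ψ-IP** — an anti-Ψ antibody captures Ψ-bearing molecules.
   Per molecule, the capture probability is
   `1 − (1 − ip_capture_eff)^k` for `k` Ψ residues, and `ip_background`
   for unmodified molecules. Bound and unbound fractions are sequenced
   separately; a pseudouridylated species is *enriched* in bound vs
   unbound.
2. **CMC + standard RT** — the carbodiimide CMC forms a bulky adduct at
   Ψ (probability `adduct_prob` per residue). Under standard reverse
   transcription an adduct stops the polymerase; for a small RNA the
   truncated cDNA is too short to map, so the molecule is effectively
   *dropped from the library*. A pseudouridylated species is therefore
   *depleted* in CMC⁺ vs mock, with closed-form survival
   `1 − stoichiometry × adduct_prob` for a single-site species.
3. **CMC + Mn²⁺ RT** — in manganese buffer the polymerase reads through
   the adduct, converting it into a 1-nt deletion (`p_del`), a random
   non-cognate base (`p_mis`), or a clean read-through. Ψ positions are
   then visible as nucleotide-resolution deletion/mismatch signatures.

The enrichment assays are tested statistically (below); the Mn²⁺ assay
is called per position with the rule: treated coverage ≥ 5 reads, at
least one altered treated read, and a ≥ 1.5-fold change of the
altered-call fraction between treated and mock.

## The synthetic data generator

The toy genome holds miRNA loci (20–24 nt), transposon (TE) copies
grouped into families with ~3% divergence from a family consensus,
tRNAs (CCA 3′ end, a U55/UNUAR block in the TΨC arm), unclassified
loci, and one rRNA-like contig with a designated list of "known" Ψ
positions. Features sit on both strands; U is stored as T.

**Expression.** Per-feature molecule shares are log-normal
(`expression_sigma`, default 1.0), fixed across libraries; the rRNA
locus receives a fixed share (`rrna_share`, default 0.15), reflecting
residual rRNA degradation products after size selection.

**Species model.** miRNA-sized loci emit their full-length product
(with probability `len_jitter` = 0.1 a 1-nt 3′ trim, emulating length
heterogeneity). Longer TE/tRNA/other loci emit a small set of discrete
species tiling the locus in a ~21-nt register with lengths 21–24 nt and
Dirichlet-distributed relative abundances — the phased-siRNA/tRF
picture of Dicer processing, under which each siRNA species is a
well-defined sequence with appreciable counts. The last species is
anchored at the 3′ end, so tRNAs shed a CCA-ending 3′ tRF. The rRNA
locus instead sheds a uniform random-window degradation cloud; its
fragments are analyzed as a coverage track, not as per-species counts.
This choice matters: with a diffuse window cloud, per-locus depletion
signals dilute below detectability, which does not reflect how discrete
small RNA species behave.

**Chemistry and sampling.** Each library draws
`molecules_per_library` molecules (default 5×10⁴) multinomially from
the species shares; Ψ occupancy, capture, adduct formation and Mn²⁺
outcomes are sampled at count level through exact multinomial
equivalents of the per-molecule Bernoulli process. IP bound + unbound
counts equal the input count exactly per replicate (a conservation
invariant); CMC treated/mock aliquots are independent draws from the
same expected composition, which is the correct marginal for an aliquot
split at these depths. A uniform per-base miscall rate
(`seq_error` = 0.001) is applied last; miscalled bases carry Phred 2 so
that base-quality-aware steps behave deterministically. All randomness
derives from `master_seed` via named substreams; identical
configurations give byte-identical FASTQ output.

**What is not modeled:** PCR duplication, ligation bias,
2′-O-methylation, UMI structure beyond optional random ends, and any
cell-sorting or AGO-specific capture beyond the generic capture model.
Passing recovery tests therefore demonstrate correctness of the
*computational* pipeline under the stated chemistry, not robustness to
library-preparation artifacts absent from the simulation.

## Read processing and alignment

Reads are adapter-trimmed (leftmost adapter occurrence or an
end-anchored prefix of ≥ 5 nt, ≤ 1 substitution, no indels — the
tolerance is configurable because published pipelines delegate it to
standard trimmers), length-filtered per branch preset (toy 15–30,
plant 20–25 or 18–30, mouse 14–44 with ≥ Q20 over 90% of bases),
N-filtered, and collapsed to unique sequences with per-library counts.

The aligner is deliberately small and fully verifiable: end-to-end
ungapped placement on both strands, ≤ 3 mismatches, with pigeonhole
k-mer seeding and an exhaustive-scan oracle in the test suite. A
deletion-aware mode admits exactly one 1-nt internal deletion (the
Mn²⁺ signature); the best stratum minimises total edits,
mismatch-only placements win ties against deletion-bearing ones, and
ambiguous deletions in homopolymers are normalised to the leftmost
reference position so pileups are deterministic. Policies: `all_best`,
`unique_only` (drop multimappers), `first_best` (one deterministic
placement, for metaplot-style single-mapping analyses). Palindromic
sequences are scanned on one strand only, since both strands give the
identical placement.

## Enrichment testing

Per-sequence counts (or per-feature aggregates) with a mean of more
than 10 raw reads per library are tested. The model follows the
standard negative-binomial count workflow:

* **Normalization** — median-of-ratios size factors; a
  `pseudo_reference` flag rescues matrices without an
  everywhere-nonzero feature.
* **Dispersion** — method of moments on normalized counts pooled
  within condition. Two details are load-bearing. First, the shot-noise
  term of a normalized count is `μ·mean(1/s)`, not `μ`: omitting the
  size factor lets small libraries (e.g. the IP bound fraction, which
  is ~5% of the input under background-only capture) masquerade their
  Poisson noise as biological dispersion, deflating every test
  statistic. Second, the signed moment estimate is kept when averaging
  into an expression-binned trend, and each feature's value is shrunk
  80% of the way toward its bin trend before flooring at 10⁻⁸: at three
  replicates the per-feature estimate is mostly noise, and keeping more
  of it (or flooring before averaging) makes the Wald test visibly
  conservative (empirical null fraction of p < 0.05 drops to ~0.02).
  With these choices the null fraction is ~0.04–0.05 on both synthetic
  Poisson matrices and full simulated null studies, while true NB
  dispersion (α = 0.2) is still recovered within [0.1, 0.4].
* **Wald test** — log2 fold change of normalized condition means with a
  0.5 pseudocount; the SE propagates the per-library NB variance
  `μ/s + αμ²` through the log; two-sided p from the normal reference;
  Benjamini–Hochberg step-up across tested features. Technical
  replicates of a biological replicate are averaged first. A strict
  pair-factor design (mean of per-pair log ratios) is available via
  `paired=True`; the default is the plain two-group contrast, the
  simpler reading of "treating the fractions as pairs".

## Site calling (Mn²⁺)

Reads from Mn²⁺ libraries are collapsed by (sequence, low-quality
positions) so base qualities survive collapsing, aligned with the
deletion-aware mode under `unique_only`, and piled up per reference
position. "Altered" = mismatch or 1-nt deletion. Two evidence rules
keep the caller silent on Ψ-free data:

* multimapped reads are excluded (a read assigned to a near-identical
  TE sibling copy would deposit the family's divergence positions as
  spurious mismatches), and
* only fully clean reads (no base below Q20) contribute altered calls —
  a read with two miscalls can be re-placed as deletion + mismatch,
  laundering flagged errors into ostensibly clean edits.

The decision rule is: treated coverage ≥ `min_reads` (5), altered
treated reads ≥ `min_alt` (1), and
`(r_t + 0.5/cov_t) / (r_m + 0.5/cov_m) ≥ min_fold` (1.5), where `r` are
altered fractions and the 0.5 add-half terms are a continuity
correction for zero-mock positions (an `exclude_zero_mock` mode drops
such positions instead). `min_alt` exists because with zero altered
reads on both sides the pseudo-ratio reduces to a pure coverage ratio.
Positions with mock coverage below `min_mock_cov` (5, mirroring
`min_reads`; no explicit mock floor is standard) are reported
untestable. Feature-level calls take the maximum fold change over the
feature's positions. Calls are monotone in both thresholds.

A residual, known limitation: genuine Ψ edits on multimapping-prone TE
species can be attributed to a sibling copy by any single-placement
scheme; family-level aggregation, not per-copy calls, is the
appropriate unit for TE conclusions.

## rRNA validation and consensus

Known rRNA Ψ sites are validated by paired coverage depletion: each
library's locus coverage is normalized to its total (plus a fixed
pseudo-share 0.5/L, keeping the track exactly invariant to depth
rescaling), log2 treated/reference ratios are averaged over pairs, and
the mean over ±2 nt (window configurable; the averaging window is not
standardised) around each site is reported, depletion negative.

Consensus support per feature: IP (padj < α and log2FC > 0), CMC
(padj < α and log2FC < 0), MnCMC (called site), with α = 0.01 by
default; the three-way intersection is the high-confidence set.

## Aggregation

TE-family × size-class rollups average member log2FC values (size
classes default 20–22/23–25 nt, configurable; sequences matching
several families count once per family, with a fractional-weight mode);
AGO preference is the argmax across AGO-IP libraries with exact ties
"ambiguous"; terminal-nucleotide composition excludes structural RNA
classes; tRFs are classified by whether the read ends at the tRNA's
3′ CCA or starts at its 5′ end, with UNUAR-motif and U55-span flags;
metagene profiles bin flanks at the window size (default 25/6
window/smooth; 50/12 for the demethylase-target preset), rescale gene
bodies to 60 bins, and apply a truncated centered moving average.
Replicate averaging is two-stage: technical within biological, then
biological — which differs measurably from pooled averaging on
unbalanced designs.

## Problem sizes

The canned study designs use 200 features (30 Ψ-modified at
stoichiometry ≥ 0.5), 5×10⁴ molecules per library and three replicate
pairs per assay — large enough that every assay's signal is governed by
its chemistry rather than by counting noise, and small enough that the
whole battery (including a 20-seed null screen for the Mn²⁺ caller,
which reuses one reference and memoizes alignments across seeds) runs
in minutes on one core. The pipeline's file-based runs in the test
suite use scaled-down references purely as smoke/determinism checks.
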