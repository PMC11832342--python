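"""Pileups, the mismatch-ratio Ψ calling rule, metaprofiles, rRNA
validation and three-assay consensus."""

import numpy as np
import pandas as pd
import pytest

from psifinder import align as al
from psifinder import pipeline as pl
from psifinder import reads_io as rio
from psifinder import sitecall as sc
from psifinder import simdata as sd


def _aln(seq, contig="c", start=0, strand="+", mm_read=(), mm_ref=(), del_ref=None):
    return al.Alignment(seq, contig, start, strand, tuple(mm_read), tuple(mm_ref),
                        del_ref)


def _profile(cov, alt):
    p = sc.PileupProfile()
    p.coverage = dict(cov)
    p.altered = dict(alt)
    return p


class TestBuildPileup:
    def test_coverage_and_mismatch_ratio(self):
        seq = "ACGTACGTAC"
        clean = _aln(seq)
        mut = _aln(seq, mm_read=(4,), mm_ref=(4,))
        prof = sc.build_pileup([(clean, 7, ()), (mut, 3, ())])
        assert prof.coverage[("c", 4)] == 10
        assert prof.altered[("c", 4)] == 3

    def test_empty_input(self):
        prof = sc.build_pileup([])
        assert prof.coverage == {} and prof.altered == {}

    def test_deletion_counts_as_altered_at_its_position(self):
        a = _aln("ACGTACGT", del_ref=3)
        prof = sc.build_pileup([(a, 5, ())])
        assert prof.coverage[("c", 3)] == 5
        assert prof.altered[("c", 3)] == 5
        # read spans 9 reference bases
        assert prof.coverage[("c", 8)] == 5

    def test_masked_reads_contribute_no_evidence(self):
        seq = "ACGTACGTAC"
        mut = _aln(seq, mm_read=(4,), mm_ref=(4,))
        prof = sc.build_pileup([(mut, 3, (7,))])
        assert ("c", 4) not in prof.altered   # read has a low-quality base
        assert ("c", 7) not in prof.coverage  # masked base call excluded
        assert prof.coverage[("c", 4)] == 3

    def test_unknown_contig_is_hard_error(self, tiny_ref):
        a = _aln("ACGTACGTAC", contig="nope")
        with pytest.raises(KeyError):
            sc.build_pileup([(a, 1, ())], ref=tiny_ref)

    def test_pileup_matches_simulator_edit_truth_without_errors(self, tiny_ref):
        truth = sd.assign_psi_sites(tiny_ref, n_modified=4, seed=3,
                                    stoich_range=(0.5, 1.0))
        cfg = sd.SimConfig(master_seed=3, molecules_per_library=4000,
                           assays=("mn",), n_mn_pairs=1, seq_error=0.0,
                           len_jitter=0.0, rrna_share=0.0)
        sim = sd.simulate_libraries(tiny_ref, truth, cfg)
        reads = pl.library_records(sim.library("mn_plus_r1"))
        masked = rio.collapse_with_masks(reads)["mn_plus_r1"]
        index = al.RefIndex(tiny_ref)
        cache = {}
        for g in masked:
            if g.sequence not in cache:
                cache[g.sequence] = al.align_with_deletions(
                    [g.sequence], index, 1, policy="unique_only")
        triples = [(cache[g.sequence][0], g.count, g.lowq)
                   for g in masked if cache[g.sequence]]
        prof = sc.build_pileup(triples, tiny_ref)
        edits = sim.edit_truth.query("library == 'mn_plus_r1'")
        for _, row in edits.iterrows():
            expected = int(row.n_del + row.n_mis)
            got = prof.altered.get((row.contig, row.pos), 0)
            assert got == expected, (row.contig, row.pos)


class TestCallPsiSites:
    def test_worked_threshold_cases(self):
        treated = _profile({("c", 1): 5}, {("c", 1): 1.5})   # ratio 0.30
        mock = _profile({("c", 1): 5}, {("c", 1): 0.5})      # ratio 0.10
        calls = sc.call_psi_sites(treated, mock)
        assert bool(calls.iloc[0].called)

        treated = _profile({("c", 1): 4}, {("c", 1): 3.6})   # ratio 0.90, 4 reads
        mock = _profile({("c", 1): 5}, {})
        calls = sc.call_psi_sites(treated, mock)
        assert not bool(calls.iloc[0].called)

        treated = _profile({("c", 1): 50}, {("c", 1): 7.0})  # 0.14 vs 0.10
        mock = _profile({("c", 1): 50}, {("c", 1): 5.0})
        calls = sc.call_psi_sites(treated, mock)
        assert not bool(calls.iloc[0].called)

    def test_low_mock_coverage_untestable(self):
        treated = _profile({("c", 1): 20}, {("c", 1): 10})
        mock = _profile({("c", 1): 2}, {})
        calls = sc.call_psi_sites(treated, mock, min_mock_cov=5)
        assert not bool(calls.iloc[0].testable)
        assert not bool(calls.iloc[0].called)

    def test_no_evidence_is_never_called(self):
        # coverage asymmetry alone must not produce a call
        treated = _profile({("c", 1): 9}, {})
        mock = _profile({("c", 1): 23}, {})
        calls = sc.call_psi_sites(treated, mock)
        assert not bool(calls.iloc[0].called)

    def test_calling_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        keys = [("c", i) for i in range(200)]
        cov_t = {k: int(rng.integers(1, 60)) for k in keys}
        alt_t = {k: int(rng.integers(0, cov_t[k] + 1)) for k in keys}
        cov_m = {k: int(rng.integers(1, 60)) for k in keys}
        alt_m = {k: int(rng.integers(0, cov_m[k] // 3 + 1)) for k in keys}
        treated, mock = _profile(cov_t, alt_t), _profile(cov_m, alt_m)
        base = sc.call_psi_sites(treated, mock).called
        for min_reads, min_fold in [(10, 1.5), (5, 2.5), (10, 2.5)]:
            harder = sc.call_psi_sites(treated, mock, min_reads=min_reads,
                                       min_fold=min_fold).called
            assert not (harder & ~base).any()

    def test_exclude_zero_mock_mode(self):
        treated = _profile({("c", 1): 20}, {("c", 1): 6})
        mock = _profile({("c", 1): 20}, {})
        add = sc.call_psi_sites(treated, mock, pseudo="add")
        assert bool(add.iloc[0].called)
        strict = sc.call_psi_sites(treated, mock, pseudo="exclude_zero_mock")
        assert not bool(strict.iloc[0].testable)


class TestPositionalMetaprofile:
    def test_all_calls_at_five_prime_position(self, tiny_ref):
        rows = []
        for f in tiny_ref.features:
            if f.cls != "miRNA" or tiny_ref.feature_seq(f)[0] != "T":
                continue
            pos = f.start if f.strand == "+" else f.end - 1
            rows.append({"contig": f.contig, "pos": pos, "called": True})
        calls = pd.DataFrame(rows)
        prof = sc.positional_metaprofile(calls, tiny_ref)
        p5 = prof[(prof.end == "5p") & (prof.position == 1)]
        assert p5.frequency.iloc[0] == 1.0
        rest = prof[~((prof.end == "5p") & (prof.position == 1))]
        assert (rest.frequency == 0).all()

    def test_no_calls_gives_zero_profile(self, tiny_ref):
        calls = pd.DataFrame(columns=["contig", "pos", "called"])
        prof = sc.positional_metaprofile(calls, tiny_ref)
        assert (prof.frequency == 0).all()

    def test_simulated_five_prime_bias_recovered(self):
        spec = sd.ReferenceSpec(mirna=sd.ClassSpec(25, 21, 22),
                                te=sd.ClassSpec(0, 0, 0), trna=sd.ClassSpec(0, 0, 0),
                                other=sd.ClassSpec(0, 0, 0), rrna_len=0,
                                mirna_start_u_frac=1.0)
        ref = sd.build_toy_reference(spec, seed=6)
        truth = sd.assign_psi_sites(ref, frac_modified_features=0.8,
                                    five_prime_bias=1.0, seed=6)
        cfg = pl.RunConfig.from_preset("toy", master_seed=6)
        from dataclasses import replace
        cfg.sim = replace(cfg.sim, molecules_per_library=20000, assays=("mn",),
                          n_mn_pairs=2, rrna_share=0.0, master_seed=6)
        sim = sd.simulate_libraries(ref, truth, cfg.sim)
        _, masked, _ = pl.preprocess(sim.libraries, cfg)
        calls, _, _ = pl.mn_site_calls(masked, ref, cfg)
        prof = sc.positional_metaprofile(calls, ref)
        top = prof.loc[prof.frequency.idxmax()]
        assert top.end == "5p" and top.position == 1


class TestRrnaValidation:
    def test_identical_pairs_give_zero_track(self):
        cov = np.full(100, 30.0)
        site_means, track = sc.rrna_site_validation(
            {"t": cov, "m": cov}, ("chrR", 0, 100), [("chrR", 50)], [("t", "m")])
        assert np.allclose(track.log2fc, 0)
        assert np.allclose(site_means, 0)

    def test_depth_rescaling_is_invariant(self):
        rng = np.random.default_rng(2)
        cov_t = rng.poisson(40, 200).astype(float) + 1
        cov_m = rng.poisson(40, 200).astype(float) + 1
        args = (("chrR", 0, 200), [("chrR", 77)], [("t", "m")])
        m1, t1 = sc.rrna_site_validation({"t": cov_t, "m": cov_m}, *args)
        m2, t2 = sc.rrna_site_validation({"t": cov_t * 2, "m": cov_m}, *args)
        assert np.allclose(t1.log2fc, t2.log2fc)
        assert np.allclose(m1, m2)

    def test_zero_coverage_library_errors(self):
        with pytest.raises(ValueError, match="zero locus coverage"):
            sc.rrna_site_validation({"t": np.zeros(50), "m": np.ones(50)},
                                    ("chrR", 0, 50), [], [("t", "m")])

    def test_planted_depletion_is_negative_at_sites(self):
        r = pl.run_rrna_experiment(seed=3, molecules=20000, n_pairs=1)
        assert (r["site_means"] < 0).all()


class TestConsensus:
    def _res(self, feats, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2FC": lfc}, index=feats)

    def test_triple_support_class(self):
        ip = self._res(["f1"], [0.001], [2.0])
        cmc = self._res(["f1"], [0.001], [-1.5])
        mn = pd.DataFrame({"called": [True]}, index=["f1"])
        table, venn = sc.consensus_calls(ip, cmc, mn, alpha=0.01)
        assert table.loc["f1", "support"] == "IP&CMC&MnCMC"
        assert venn["IP&CMC&MnCMC"] == 1

    def test_cmc_sign_convention(self):
        ip = self._res(["f1"], [0.001], [2.0])
        cmc = self._res(["f1"], [0.001], [1.5])  # enriched, not depleted
        mn = pd.DataFrame({"called": [False]}, index=["f1"])
        table, _ = sc.consensus_calls(ip, cmc, mn, alpha=0.01)
        assert not table.loc["f1", "CMC"]
        assert table.loc["f1", "support"] == "IP"

    def test_union_universe(self):
        ip = self._res(["f1"], [0.5], [0.1])
        cmc = self._res(["f2"], [0.5], [0.1])
        mn = pd.DataFrame({"called": [True]}, index=["f3"])
        table, venn = sc.consensus_calls(ip, cmc, mn)
        assert set(table.index) == {"f1", "f2", "f3"}
        assert venn["MnCMC"] == 1
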