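"""Family rollups, AGO preference, terminal composition, tRFs, metaplots."""

import numpy as np
import pandas as pd
import pytest

from psifinder import aggregate as ag
from psifinder import align as al
from psifinder import simdata as sd


def _annot(rows):
    return pd.DataFrame(rows).set_index("sequence")


class TestFamilyAggregation:
    def test_mean_of_member_fold_changes(self):
        enr = pd.DataFrame({"log2FC": [1.0, 3.0]}, index=["AAA" * 7, "CCC" * 7])
        annot = _annot([
            {"sequence": "AAA" * 7, "families": "famA", "length": 21},
            {"sequence": "CCC" * 7, "families": "famA", "length": 21},
        ])
        out = ag.aggregate_family_enrichment(enr, annot)
        assert len(out) == 1
        assert out.iloc[0].mean_log2FC == 2.0
        assert out.iloc[0].n == 2

    def test_size_class_assignment_is_exclusive(self):
        seq = "A" * 23
        enr = pd.DataFrame({"log2FC": [1.0]}, index=[seq])
        annot = _annot([{"sequence": seq, "families": "famA", "length": 23}])
        out = ag.aggregate_family_enrichment(enr, annot)
        assert list(out.size_class) == ["23-25"]

    def test_multi_family_sequence_counts_in_each(self):
        seq = "G" * 21
        enr = pd.DataFrame({"log2FC": [2.0]}, index=[seq])
        annot = _annot([{"sequence": seq, "families": "famA,famB", "length": 21}])
        out = ag.aggregate_family_enrichment(enr, annot)
        assert set(out.family) == {"famA", "famB"}

    def test_brute_force_group_by_oracle(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(200)]
        fams = [f"fam{rng.integers(0, 10)}" for _ in seqs]
        lfc = rng.normal(size=200)
        enr = pd.DataFrame({"log2FC": lfc}, index=seqs)
        annot = _annot([{"sequence": s, "families": f, "length": 21}
                        for s, f in zip(seqs, fams)])
        out = ag.aggregate_family_enrichment(enr, annot).set_index("family")
        expect = pd.Series(lfc, index=fams).groupby(level=0).mean()
        for fam, val in expect.items():
            assert abs(out.loc[fam, "mean_log2FC"] - val) < 1e-12

    def test_two_stage_replicate_averaging_differs_from_pooling(self):
        vals = pd.DataFrame([[1.0, 1.0, 4.0]], columns=["a1", "a2", "b1"])
        tech_of = {"a1": "A", "a2": "A", "b1": "B"}
        two_stage = ag.average_replicates(vals, tech_of).iloc[0]
        pooled = vals.iloc[0].mean()
        assert two_stage == 2.5
        assert pooled == 2.0
        assert two_stage != pooled


class TestAgoPreference:
    def test_argmax_and_tie(self):
        df = pd.DataFrame({"AGO1": [0.5, 1.0], "AGO5": [2.0, 1.0], "AGO9": [1.0, 0.2]},
                          index=pd.MultiIndex.from_tuples(
                              [("famA", "20-22"), ("famB", "20-22")]))
        out = ag.assign_ago_preference(df)
        assert out.preferred_ago.tolist() == ["AGO5", "ambiguous"]

    def test_column_order_invariance(self):
        df = pd.DataFrame({"AGO1": [0.5], "AGO5": [2.0], "AGO9": [1.0]},
                          index=["famA"])
        a = ag.assign_ago_preference(df).preferred_ago.tolist()
        b = ag.assign_ago_preference(df[["AGO9", "AGO5", "AGO1"]]).preferred_ago.tolist()
        assert a == b

    def test_requires_two_libraries(self):
        with pytest.raises(ValueError):
            ag.assign_ago_preference(pd.DataFrame({"AGO1": [1.0]}, index=["f"]))


class TestTerminalComposition:
    def test_all_sequences_start_with_u(self):
        out = ag.terminal_nt_composition({"g": ["TACG", "TGGA", "TCCA"]})
        u5 = out[(out.group == "g") & (out.end == "5p") & (out.base == "U")]
        assert u5.frequency.iloc[0] == 1.0

    def test_single_sequence(self):
        out = ag.terminal_nt_composition({"g": ["TGCA"]})
        assert out[(out.end == "5p") & (out.base == "U")].frequency.iloc[0] == 1.0
        assert out[(out.end == "3p") & (out.base == "A")].frequency.iloc[0] == 1.0

    def test_uniform_sequences_near_quarter(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(4000)]
        out = ag.terminal_nt_composition({"g": seqs})
        freqs = out[out.end == "5p"].frequency
        band = 3 * np.sqrt(0.25 * 0.75 / 4000)
        assert (abs(freqs - 0.25) < band + 1e-9).all()

    def test_structural_rna_classes_excluded(self):
        annot = _annot([{"sequence": "TAAA", "classes": "tRNA"},
                        {"sequence": "GAAA", "classes": "miRNA"}])
        out = ag.terminal_nt_composition({"g": ["TAAA", "GAAA"]}, annot=annot)
        g5 = out[(out.end == "5p") & (out.base == "G")]
        assert g5.frequency.iloc[0] == 1.0  # only the miRNA sequence remains

    def test_frequencies_sum_to_one(self):
        out = ag.terminal_nt_composition({"g": ["ACGT", "GTAC", "TTTT"]})
        sums = out.groupby(["group", "end"]).frequency.sum()
        assert np.allclose(sums, 1.0)


class TestTrfs:
    def _trna(self, tiny_ref):
        return [f for f in tiny_ref.features if f.cls == "tRNA"]

    def test_three_prime_trf_ends_at_cca(self, tiny_ref):
        f = self._trna(tiny_ref)[0]
        seq = tiny_ref.feature_seq(f)[-22:]
        hits = al.align_reads([seq], tiny_ref, 0)
        out = ag.extract_trfs(hits, tiny_ref)
        assert (out.trf_class == "3p_tRF").any()

    def test_five_prime_and_internal_classes(self, tiny_ref):
        f = self._trna(tiny_ref)[0]
        whole = tiny_ref.feature_seq(f)
        five = whole[:20]
        internal = whole[10:32]
        hits = al.align_reads([five, internal], tiny_ref, 0)
        out = ag.extract_trfs(hits, tiny_ref).set_index("sequence")
        assert out.loc[five, "trf_class"] == "5p_tRF"
        assert out.loc[internal, "trf_class"] == "internal"

    def test_unuar_motif_flag(self, tiny_ref):
        f = self._trna(tiny_ref)[0]
        # generated tRNAs carry the UNUAR block at offsets 52-56
        read = tiny_ref.feature_seq(f)[45:70]
        hits = al.align_reads([read], tiny_ref, 0)
        out = ag.extract_trfs(hits, tiny_ref).set_index("sequence")
        assert bool(out.loc[read, "unuar"])
        assert bool(out.loc[read, "spans_psi55"])

    def test_motif_regex_semantics(self):
        assert ag.UNUAR_RE.search("CATATAGCC")   # U.UA[AG] on DNA letters
        assert not ag.UNUAR_RE.search("CATTTTGCC")

    def test_classification_matches_coordinate_recomputation(self, tiny_ref):
        rng = np.random.default_rng(4)
        reads = []
        for f in self._trna(tiny_ref):
            whole = tiny_ref.feature_seq(f)
            for _ in range(5):
                ln = int(rng.integers(18, 30))
                off = int(rng.integers(0, len(whole) - ln + 1))
                reads.append((whole[off:off + ln], off, off + ln == len(whole)))
        hits = al.align_reads([r[0] for r in reads], tiny_ref, 0,
                              policy="unique_only")
        out = ag.extract_trfs(hits, tiny_ref).set_index("sequence")
        for seq, off, at_end in reads:
            if seq not in out.index:
                continue
            rec = out.loc[seq].iloc[0] if isinstance(out.loc[seq], pd.DataFrame) \
                else out.loc[seq]
            if at_end:
                assert rec.trf_class == "3p_tRF"
            elif off == 0:
                assert rec.trf_class == "5p_tRF"
            else:
                assert rec.trf_class == "internal"


class TestMetaplot:
    def _cov(self, tracks):
        return {lib: {c: np.asarray(v, dtype=float) for c, v in t.items()}
                for lib, t in tracks.items()}

    def test_uniform_coverage_gives_flat_profile(self):
        genes = [sd.Feature("g1", "c", 200, 400, "+", "other")]
        cov = self._cov({"L1": {"c": np.full(1000, 3.0)}})
        prof = ag.metaplot_profile(cov, {"L1": "x"}, genes, flank=100,
                                   body_bins=20, window=25, smooth=3)
        vals = prof.values["x"].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_hand_computed_moving_average(self):
        out = ag.moving_average(np.array([0, 0, 6, 0, 0], dtype=float), 3)
        assert np.allclose(out, [0, 2, 2, 2, 0])

    def test_minus_strand_gene_mirrors_plus(self):
        rng = np.random.default_rng(5)
        track = rng.poisson(20, 1000).astype(float)
        plus = [sd.Feature("g", "c", 300, 500, "+", "other")]
        minus = [sd.Feature("g", "c", 300, 500, "-", "other")]
        cov_p = self._cov({"L1": {"c": track}})
        cov_m = self._cov({"L1": {"c": track[::-1].copy()}})
        # reversing the genome and flipping the strand must give the same profile
        p1 = ag.metaplot_profile(cov_p, {"L1": "x"},
                                 [sd.Feature("g", "c", 300, 500, "+", "other")],
                                 flank=100, body_bins=20, window=25, smooth=1)
        p2 = ag.metaplot_profile(cov_m, {"L1": "x"},
                                 [sd.Feature("g", "c", 500, 700, "-", "other")],
                                 flank=100, body_bins=20, window=25, smooth=1)
        assert np.allclose(p1.values["x"], p2.values["x"])

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        track = rng.poisson(20, 800).astype(float) + 1
        genes = [sd.Feature("g", "c", 200, 500, "+", "other")]
        p1 = ag.metaplot_profile(self._cov({"L1": {"c": track}}), {"L1": "x"},
                                 genes, flank=100, body_bins=10, window=25, smooth=1)
        p2 = ag.metaplot_profile(self._cov({"L1": {"c": track * 7}}), {"L1": "x"},
                                 genes, flank=100, body_bins=10, window=25, smooth=1)
        assert np.allclose(p1.values["x"], p2.values["x"])

    def test_flank_must_be_window_multiple(self):
        genes = [sd.Feature("g", "c", 100, 200, "+", "other")]
        with pytest.raises(ValueError):
            ag.metaplot_profile(self._cov({"L1": {"c": np.ones(500)}}), {"L1": "x"},
                                genes, flank=110, window=25)

    def test_smoothing_preserves_total_within_tolerance(self):
        rng = np.random.default_rng(7)
        x = rng.poisson(10, 60).astype(float)
        sm = ag.moving_average(x, 6)
        assert abs(sm.sum() - x.sum()) / x.sum() < 0.1
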