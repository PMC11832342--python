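"""Count matrices, median-of-ratios normalization, NB dispersion and the
Wald enrichment test."""

import numpy as np
import pandas as pd
import pytest

from psifinder import enrich as en
from psifinder.reads_io import CollapsedRead


def _meta(conditions, pairs=None):
    n = len(conditions)
    pairs = pairs or [f"p{i % (n // 2)}" for i in range(n)]
    return pd.DataFrame({
        "assay": "x", "condition": conditions, "pair": pairs,
        "replicate": [i % (n // 2) + 1 for i in range(n)], "tech": 1,
    }, index=[f"L{i}" for i in range(n)])


def _matrix(arr, conditions):
    counts = pd.DataFrame(np.asarray(arr),
                          index=[f"f{i}" for i in range(len(arr))],
                          columns=[f"L{i}" for i in range(len(conditions))])
    return en.CountMatrix(counts, _meta(conditions))


class TestBuildCountMatrix:
    def test_mean_filter_is_strict(self):
        meta = _meta(["t", "t", "t", "r", "r", "r"])[:3]
        kept = CollapsedRead("ACGTACGTACGTACGTACGTA", {"L0": 11, "L1": 11, "L2": 11})
        gone = CollapsedRead("TGCATGCATGCATGCATGCAT", {"L0": 10, "L1": 10, "L2": 10})
        cm = en.build_count_matrix([kept, gone], meta, min_mean=10)
        assert list(cm.counts.index) == [kept.sequence]
        cm = en.build_count_matrix([kept, gone], meta, min_mean=10, strict=False)
        assert len(cm.counts) == 2

    def test_empty_input(self):
        cm = en.build_count_matrix([], _meta(["t", "r"]), min_mean=0)
        assert cm.counts.empty

    def test_column_sums_match_library_read_counts(self, tiny_sim):
        from psifinder import reads_io as rio
        from psifinder import pipeline as pl
        reads = [r for lib in tiny_sim.libraries for r in pl.library_records(lib)]
        collapsed = rio.collapse_reads(reads)
        meta = en.metadata_from_sim(tiny_sim)
        cm = en.build_count_matrix(collapsed, meta, min_mean=-1)
        for lib in tiny_sim.libraries:
            assert cm.counts[lib.label].sum() == len(lib.reads)

    def test_missing_metadata_is_hard_error(self):
        collapsed = [CollapsedRead("ACGT", {"LX": 5})]
        with pytest.raises(ValueError):
            en.build_count_matrix(collapsed, _meta(["t", "r"]), min_mean=0)


class TestSizeFactors:
    def test_identical_libraries_get_unit_factors(self):
        counts = pd.DataFrame({"L0": [5, 9, 20], "L1": [5, 9, 20]})
        sf = en.compute_size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_hand_computed_example(self):
        counts = pd.DataFrame({"L0": [2, 8], "L1": [4, 16]})
        sf = en.compute_size_factors(counts)
        assert np.allclose(sf, [0.7071067811865476, 1.4142135623730951])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (40, 4)),
                              columns=[f"L{i}" for i in range(4)])
        sf = en.compute_size_factors(counts)
        scaled = counts.copy()
        scaled["L2"] *= 4
        sf2 = en.compute_size_factors(scaled)
        # the scaled library's factor grows 4x up to the geometric-mean reference
        gm_shift = 4 ** (1 / 4)
        assert np.isclose(sf2["L2"] / sf["L2"], 4 / gm_shift, rtol=1e-9)

    def test_invariant_to_feature_order_and_duplication(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, (30, 3)),
                              index=[f"f{i}" for i in range(30)],
                              columns=list("ABC"))
        sf = en.compute_size_factors(counts)
        shuffled = counts.sample(frac=1, random_state=2)
        assert np.allclose(en.compute_size_factors(shuffled), sf)
        doubled = pd.concat([counts, counts.rename(index=lambda s: s + "_dup")])
        assert np.allclose(en.compute_size_factors(doubled), sf)

    def test_brute_force_oracle_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = pd.DataFrame(rng.poisson(rng.uniform(5, 80), (50, 6)) + 1,
                                  columns=[f"L{i}" for i in range(6)])
            sf = en.compute_size_factors(counts)
            logg = np.log(counts.to_numpy()).mean(axis=1)
            expect = np.median(counts.to_numpy() / np.exp(logg)[:, None], axis=0)
            assert np.allclose(sf.to_numpy(), expect, atol=1e-9)

    def test_no_common_feature_errors_and_fallback(self):
        counts = pd.DataFrame({"L0": [5, 0], "L1": [0, 5]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            en.compute_size_factors(counts)
        sf = en.compute_size_factors(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersion:
    def _run(self, counts, conditions=("t", "t", "t", "r", "r", "r")):
        counts = pd.DataFrame(counts, columns=[f"L{i}" for i in range(6)])
        sf = pd.Series(1.0, index=counts.columns)
        cond = pd.Series(list(conditions), index=counts.columns)
        return en.estimate_dispersion(counts, sf, cond)

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(0)
        disp = self._run(rng.poisson(100, (500, 6)))
        assert disp.median() <= 0.01

    def test_nb_counts_recover_dispersion(self):
        rng = np.random.default_rng(1)
        alpha, mu = 0.2, 100
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mu), (500, 6))
        disp = self._run(counts)
        assert 0.1 <= disp.median() <= 0.4

    def test_constant_counts_hit_floor(self):
        disp = self._run(np.full((20, 6), 7))
        assert np.allclose(disp, 1e-8)

    def test_single_replicate_falls_back_with_warning(self, caplog):
        counts = pd.DataFrame({"L0": [5, 9], "L1": [7, 11]})
        sf = pd.Series(1.0, index=counts.columns)
        cond = pd.Series(["t", "r"], index=counts.columns)
        with caplog.at_level("WARNING"):
            disp = en.estimate_dispersion(counts, sf, cond)
        assert np.allclose(disp, 1e-8)
        assert any("replicate" in r.message for r in caplog.records)


class TestBH:
    def test_hand_worked_step_up(self):
        adj = en.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            expect = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(en.bh_adjust(p), expect, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        adj = en.bh_adjust(p)
        assert ((adj >= p - 1e-15) & (adj <= 1.0)).all()


class TestWald:
    def test_identical_means_give_null_result(self):
        cm = _matrix(np.tile([[10, 10, 10, 10, 10, 10]], (5, 1)),
                     ["t", "t", "t", "r", "r", "r"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(1e-8, index=cm.counts.index)
        res = en.test_enrichment(cm, sf, disp, ("t", "r"))
        assert np.allclose(res.log2FC, 0) and np.allclose(res.stat, 0)
        assert np.allclose(res.pvalue, 1)

    @pytest.mark.parametrize("paired", [False, True])
    def test_contrast_swap_negates_lfc_preserves_p(self, paired):
        rng = np.random.default_rng(5)
        cm = _matrix(rng.poisson(40, (30, 6)), ["t", "t", "t", "r", "r", "r"])
        sf = en.compute_size_factors(cm.counts)
        disp = en.estimate_dispersion(cm.counts, sf, cm.meta.condition)
        fwd = en.test_enrichment(cm, sf, disp, ("t", "r"), paired=paired)
        rev = en.test_enrichment(cm, sf, disp, ("r", "t"), paired=paired)
        assert np.allclose(fwd.log2FC, -rev.log2FC)
        assert np.allclose(fwd.pvalue, rev.pvalue)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(6)
        cm = _matrix(rng.poisson(40, (60, 6)), ["t", "t", "t", "r", "r", "r"])
        sf = en.compute_size_factors(cm.counts)
        disp = en.estimate_dispersion(cm.counts, sf, cm.meta.condition)
        res = en.test_enrichment(cm, sf, disp, ("t", "r"))
        assert (res.padj >= res.pvalue - 1e-15).all()

    def test_unmatched_pairs_hard_error(self):
        cm = _matrix(np.full((4, 4), 20), ["t", "t", "r", "r"])
        cm.meta["pair"] = ["p0", "p1", "p0", "p9"]
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(1e-8, index=cm.counts.index)
        with pytest.raises(ValueError, match="pair"):
            en.test_enrichment(cm, sf, disp, ("t", "r"))

    def test_technical_replicates_averaged_before_testing(self):
        # two technical replicates of one biological replicate must count once
        counts = pd.DataFrame(
            [[30, 30, 10, 20, 20]] * 10,
            index=[f"f{i}" for i in range(10)],
            columns=[f"L{i}" for i in range(5)], dtype=int)
        meta = pd.DataFrame({
            "assay": "x",
            "condition": ["t", "t", "t", "r", "r"],
            "pair": ["p0", "p0", "p1", "p0", "p1"],
            "replicate": [1, 1, 2, 1, 2],
            "tech": [1, 2, 1, 1, 1],
        }, index=counts.columns)
        cm = en.CountMatrix(counts, meta)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(1e-8, index=counts.index)
        res = en.test_enrichment(cm, sf, disp, ("t", "r"))
        # tech-average: (30+30)/2=30 then mean(30,10)=20 == reference mean
        assert np.allclose(res.log2FC, 0)

    def test_strong_depletion_detected(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(200, (50, 6))
        base[0, :3] = rng.poisson(40, 3)  # one depleted feature
        cm = _matrix(base, ["t", "t", "t", "r", "r", "r"])
        sf = en.compute_size_factors(cm.counts)
        disp = en.estimate_dispersion(cm.counts, sf, cm.meta.condition)
        res = en.test_enrichment(cm, sf, disp, ("t", "r"))
        assert res.iloc[0].padj < 0.001 and res.iloc[0].log2FC < -1
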