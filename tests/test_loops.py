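import numpy as np
import pandas as pd
import pytest

from stiffchrom import (
    classify_loops,
    deduplicate_loops,
    ice_balance,
    paired_pileup_test,
    pileup,
    plant_loops,
    synth_contact_map,
)
from stiffchrom.loops import PileupResult
from stiffchrom.synth import SyntheticTruth


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestDedup:
    def test_same_loop_two_resolutions_keeps_finer(self, loops_frame_factory):
        loops = loops_frame_factory(
            [
                ("chr1", 100_000, 101_000, "chr1", 300_000, 301_000, 1000, "x"),
                ("chr1", 102_000, 106_000, "chr1", 298_000, 302_000, 4000, "x"),
            ]
        )
        out = deduplicate_loops(loops)
        assert len(out) == 1
        assert out.iloc[0]["resolution_bp"] == 1000
        assert out.iloc[0]["startA"] == 100_000

    def test_distant_loops_kept(self, loops_frame_factory):
        loops = loops_frame_factory(
            [
                ("chr1", 100_000, 101_000, "chr1", 300_000, 301_000, 1000, "x"),
                ("chr1", 150_000, 151_000, "chr1", 350_000, 351_000, 1000, "x"),
            ]
        )
        assert len(deduplicate_loops(loops)) == 2

    def test_transitive_chain_merges_to_one(self, loops_frame_factory):
        # pairwise within 20 kb along a chain: single-linkage merge
        loops = loops_frame_factory(
            [
                ("chr1", 100_000, 104_000, "chr1", 300_000, 304_000, 4000, "x"),
                ("chr1", 115_000, 119_000, "chr1", 315_000, 319_000, 4000, "x"),
                ("chr1", 130_000, 131_000, "chr1", 330_000, 331_000, 1000, "x"),
            ]
        )
        out = deduplicate_loops(loops)
        assert len(out) == 1
        assert out.iloc[0]["resolution_bp"] == 1000

    def test_matches_bruteforce_clustering_oracle(self, loops_frame_factory):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(40):
            a = int(rng.integers(0, 2_000_000))
            b = a + int(rng.integers(100_000, 500_000))
            res = int(rng.choice([1000, 4000]))
            rows.append(("chr1", a, a + res, "chr1", b, b + res, res, "x"))
        loops = loops_frame_factory(rows)
        out = deduplicate_loops(loops, window_bp=20_000)

        # oracle: O(n^2) single-linkage clusters on anchor midpoints
        ma = (loops["startA"] + loops["endA"]) // 2
        mb = (loops["startB"] + loops["endB"]) // 2
        n = len(loops)
        adj = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if abs(ma[i] - ma[j]) <= 20_000 and abs(mb[i] - mb[j]) <= 20_000
        ]
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(adj)
        assert len(out) == nx.number_connected_components(g)

    def test_never_grows_and_order_independent(self, loops_frame_factory):
        rng = np.random.default_rng(8)
        rows = []
        for _ in range(25):
            a = int(rng.integers(0, 500_000))
            b = a + int(rng.integers(50_000, 200_000))
            rows.append(("chr1", a, a + 4000, "chr1", b, b + 4000,
                         int(rng.choice([1000, 4000])), "x"))
        loops = loops_frame_factory(rows)
        out1 = deduplicate_loops(loops)
        assert len(out1) <= len(loops)
        shuffled = loops.sample(frac=1, random_state=1).reset_index(drop=True)
        out2 = deduplicate_loops(shuffled)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_in_empty_out(self, loops_frame_factory):
        assert len(deduplicate_loops(loops_frame_factory([]))) == 0


class TestClassify:
    @pytest.fixture
    def one_loop(self, loops_frame_factory):
        return loops_frame_factory(
            [("chr1", 10_000, 11_000, "chr1", 50_000, 51_000, 1000, "tsa")]
        )

    def test_ctcf_when_both_anchors_proximal(self, one_loop):
        peaks = {"CTCF": bed([("chr1", 10_500, 10_600), ("chr1", 50_200, 50_300)])}
        out = classify_loops(one_loop, peaks)
        assert out.iloc[0]["ctcf_class"] == "CTCF"

    def test_non_ctcf_needs_clearance(self, one_loop):
        # peak 3 kb away from anchor A, nothing near anchor B
        peaks = {"CTCF": bed([("chr1", 14_100, 14_200)])}
        out = classify_loops(one_loop, peaks)
        assert out.iloc[0]["ctcf_class"] == "non-CTCF"

    def test_gap_between_rules_is_ambiguous(self, one_loop):
        # peak at 1.5 kb: neither within 1 kb nor beyond 2.5 kb
        peaks = {"CTCF": bed([("chr1", 12_500, 12_600)])}
        out = classify_loops(one_loop, peaks)
        assert out.iloc[0]["ctcf_class"] == "ambiguous"

    def test_either_anchor_mode(self, one_loop):
        peaks = {"CTCF": bed([("chr1", 10_500, 10_600)])}
        strict = classify_loops(one_loop, peaks)
        loose = classify_loops(one_loop, peaks, ctcf_both_anchors=False)
        assert strict.iloc[0]["ctcf_class"] == "ambiguous"
        assert loose.iloc[0]["ctcf_class"] == "CTCF"

    def test_repressive_overlap(self, one_loop):
        peaks = {"H3K27me3": bed([("chr1", 10_800, 11_500)])}
        out = classify_loops(one_loop, peaks)
        assert bool(out.iloc[0]["repressive"])
        assert not bool(out.iloc[0]["active"])
        assert out.iloc[0]["ctcf_class"] == "non-CTCF"

    def test_tss_within_2kb(self, one_loop):
        tss = bed([("chr1", 52_500, 52_501)])
        out = classify_loops(one_loop, {}, tss=tss)
        assert bool(out.iloc[0]["tss_loop"])

    def test_de_novo_h3k9me3_requires_unique_condition(self, one_loop):
        peaks = {"H3K9me3": bed([("chr1", 10_500, 11_200)])}
        out = classify_loops(one_loop, peaks, unique_conditions={"tsa"})
        assert bool(out.iloc[0]["de_novo_h3k9me3"])
        out2 = classify_loops(one_loop, peaks, unique_conditions={"dmso"})
        assert not bool(out2.iloc[0]["de_novo_h3k9me3"])

    def test_empty_peaks_all_non_ctcf(self, one_loop):
        out = classify_loops(one_loop, {})
        assert out.iloc[0]["ctcf_class"] == "non-CTCF"
        assert not out.iloc[0][["active", "repressive"]].any()

    def test_unknown_mark_rejected(self, one_loop):
        with pytest.raises(ValueError, match="unknown mark"):
            classify_loops(one_loop, {"H3K99me9": bed([])})

    def test_idempotent_and_order_independent(self, loops_frame_factory):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(20):
            a = int(rng.integers(0, 900_000))
            b = a + int(rng.integers(100_000, 400_000))
            rows.append(("chr1", a, a + 1000, "chr1", b, b + 1000, 1000, "x"))
        loops = loops_frame_factory(rows)
        peaks = {
            "CTCF": bed([("chr1", int(p), int(p) + 200)
                         for p in rng.integers(0, 1_300_000, 30)]),
            "H3K27ac": bed([("chr1", int(p), int(p) + 500)
                            for p in rng.integers(0, 1_300_000, 20)]),
        }
        out1 = classify_loops(loops, peaks)
        out2 = classify_loops(out1[loops.columns], peaks)
        pd.testing.assert_frame_equal(out1, out2)
        shuffled = loops.sample(frac=1, random_state=5).reset_index(drop=True)
        out3 = classify_loops(shuffled, peaks)
        pd.testing.assert_frame_equal(out1, out3)


def _loops_from_truth(truth):
    res = truth.resolution
    return pd.DataFrame(
        {
            "chromA": truth.loops["chrom"],
            "startA": truth.loops["bin1"] * res,
            "endA": (truth.loops["bin1"] + 1) * res,
            "chromB": truth.loops["chrom"],
            "startB": truth.loops["bin2"] * res,
            "endB": (truth.loops["bin2"] + 1) * res,
            "resolution_bp": res,
            "source_condition": "synth",
        }
    )


class TestPileup:
    def test_uniform_map_scores_one(self):
        truth = SyntheticTruth(s=0.0)
        cmap = synth_contact_map(truth, depth=4e6, replicate_seed=3)
        ice_balance(cmap)
        loops = _loops_from_truth(plant_loops(truth, 20, seed=5))
        pile = pileup(cmap, loops, flank_bp=5 * truth.resolution)
        assert pile.central_score == pytest.approx(1.0, abs=0.15)

    def test_planted_enrichment_recovered(self):
        # compartment-free truth isolates the loop factor: planted loops are
        # multiplicative over the checkerboard, so a nonzero amplitude adds a
        # +-s background to the central pixels that is not loop signal
        truth = plant_loops(SyntheticTruth(s=0.0), n_loops=40, seed=11)
        vals = []
        for seed in (1, 2):
            cmap = synth_contact_map(truth, depth=5e6, replicate_seed=seed)
            ice_balance(cmap)
            loops = _loops_from_truth(truth)
            pile = pileup(cmap, loops, flank_bp=5 * truth.resolution)
            vals.append(pile.central_score)
        assert np.mean(vals) == pytest.approx(3.0, abs=0.3)

    def test_central_window_has_nine_values(self, truth_with_loops, synthetic_map):
        if synthetic_map.weights is None:
            ice_balance(synthetic_map)
        loops = _loops_from_truth(truth_with_loops)
        pile = pileup(synthetic_map, loops, flank_bp=5 * truth_with_loops.resolution)
        assert pile.central_values.shape == (9,)
        assert pile.matrix.shape == (11, 11)

    def test_out_of_bounds_loops_skipped(self, synthetic_map, loops_frame_factory):
        if synthetic_map.weights is None:
            ice_balance(synthetic_map)
        res = synthetic_map.resolution
        loops = loops_frame_factory(
            [
                ("chr1", 0, res, "chr1", 3 * res, 4 * res, res, "x"),  # hits edge
                ("chr1", 100 * res, 101 * res, "chr1", 140 * res, 141 * res, res, "x"),
            ]
        )
        pile = pileup(synthetic_map, loops, flank_bp=5 * res)
        assert pile.n_skipped == 1
        assert pile.n_loops == 1

    def test_pileup_of_identical_windows_equals_single(self, synthetic_map,
                                                       loops_frame_factory):
        if synthetic_map.weights is None:
            ice_balance(synthetic_map)
        res = synthetic_map.resolution
        row = ("chr1", 50 * res, 51 * res, "chr1", 80 * res, 81 * res, res, "x")
        one = pileup(synthetic_map, loops_frame_factory([row]), flank_bp=3 * res)
        # same window listed via two loops at identical coordinates after
        # shifting by < 1 bin keeps the lifted pixel identical
        row2 = ("chr1", 50 * res + 1, 51 * res + 1, "chr1", 80 * res, 81 * res, res, "y")
        many = pileup(
            synthetic_map, loops_frame_factory([row, row2]), flank_bp=3 * res
        )
        assert np.allclose(one.matrix, many.matrix, equal_nan=True)


class TestPairedTest:
    def _pile(self, matrix):
        return PileupResult(matrix=np.asarray(matrix, dtype=float), n_loops=1, n_skipped=0)

    def test_identical_piles_degenerate(self):
        m = np.arange(25.0).reshape(5, 5)
        t, p, degen = paired_pileup_test(self._pile(m), self._pile(m))
        assert degen and p == 1.0

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 3, size=(5, 5))
        b = a + rng.normal(0.3, 0.2, size=(5, 5))
        t, p, degen = paired_pileup_test(self._pile(a), self._pile(b))
        assert not degen
        # textbook paired t on the central 9 pixels
        ca = a[1:4, 1:4].ravel()
        cb = b[1:4, 1:4].ravel()
        d = ca - cb
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(9))
        from scipy import stats

        p_ref = 2 * stats.t.sf(abs(t_ref), 8)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_planted_difference_detected(self, truth_with_loops):
        from dataclasses import replace

        weak = replace(truth_with_loops, loops=truth_with_loops.loops.assign(enrichment=1.0))
        strong = truth_with_loops
        loops = _loops_from_truth(truth_with_loops)
        piles = []
        for tr in (weak, strong):
            cmap = synth_contact_map(tr, depth=3e6, replicate_seed=4)
            ice_balance(cmap)
            piles.append(pileup(cmap, loops, flank_bp=5 * tr.resolution))
        t, p, degen = paired_pileup_test(piles[0], piles[1])
        assert not degen
        assert p < 0.01
        assert t < 0  # second condition stronger

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            paired_pileup_test(
                self._pile(np.ones((5, 5))), self._pile(np.ones((7, 7)))
            )
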