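import numpy as np
import pandas as pd
import pytest

from stiffchrom import (
    ContactMap,
    compartment_strength,
    eigen_compartments,
    expected_cis,
    ice_balance,
    make_bins,
    match_cis_depth,
    oe,
    saddle,
    synth_contact_map,
)
from stiffchrom.mapcore import dense_to_pixels
from stiffchrom.synth import SyntheticTruth
from stiffchrom import io as sio


def ice_oracle(C, n_iter=10_000):
    """Brute-force fixed-point iteration for the balancing weights."""
    b = np.ones(C.shape[0])
    for _ in range(n_iter):
        m = (C * b[:, None] * b[None, :]).sum(axis=1)
        b /= np.sqrt(m / m.mean())
    m = (C * b[:, None] * b[None, :]).sum(axis=1)
    return b / np.sqrt(m.mean())


def test_balanced_2x2_weights_equal_up_to_scale(map_from_dense_factory):
    C = np.array([[0.0, 5.0], [5.0, 0.0]])
    cmap = map_from_dense_factory(C)
    w = ice_balance(cmap, mask_quantile=0.0)
    assert np.isfinite(w).all()
    assert w[0] == pytest.approx(w[1])


def test_ice_matches_bruteforce_oracle(map_from_dense_factory):
    rng = np.random.default_rng(3)
    C = rng.uniform(1, 10, size=(6, 6))
    C = np.triu(C, 1)
    C = C + C.T
    cmap = map_from_dense_factory(C)
    w = ice_balance(cmap, tol=1e-10, max_iter=10_000, mask_quantile=0.0)
    expected = ice_oracle(C)
    assert np.allclose(w, expected, rtol=1e-6)
    # row sums of the balanced matrix are uniform
    B = cmap.balanced()
    marg = B.sum(axis=1)
    assert np.std(marg) / np.mean(marg) < 1e-8


def test_ice_masks_zero_coverage_bin(map_from_dense_factory):
    rng = np.random.default_rng(4)
    C = rng.uniform(1, 5, size=(6, 6))
    C = np.triu(C, 1) + np.triu(C, 1).T
    C[2, :] = C[:, 2] = 0.0
    cmap = map_from_dense_factory(C)
    w = ice_balance(cmap, mask_quantile=0.0)
    assert np.isnan(w[2])
    assert np.isfinite(np.delete(w, 2)).all()
    B = cmap.balanced()
    assert np.isnan(B[2]).all()  # masked bins propagate as missing


def test_ice_idempotent(synthetic_map):
    w1 = ice_balance(synthetic_map, tol=1e-8, max_iter=2000).copy()
    # balancing the already-balanced matrix yields ~unit weights
    ok = np.isfinite(w1)
    B = synthetic_map.balanced()
    B[~np.isfinite(B)] = 0.0
    rebal = ContactMap(
        bins=synthetic_map.bins,
        pixels=dense_to_pixels(np.triu(B)),
        resolution=synthetic_map.resolution,
    )
    w2 = ice_balance(rebal, tol=1e-8, max_iter=2000, mask_quantile=0.0)
    ratio = w2[ok] / np.nanmean(w2[ok])
    assert np.nanstd(ratio) < 1e-3


def test_ice_needs_two_bins(map_from_dense_factory):
    with pytest.raises(ValueError):
        ice_balance(map_from_dense_factory(np.zeros((1, 1))))


def test_expected_decay_slope_matches_generator():
    truth = SyntheticTruth(s=0.0, alpha=1.0)
    cmap = synth_contact_map(truth, depth=4e6, replicate_seed=9)
    ice_balance(cmap)
    exp = expected_cis(cmap)
    d = np.arange(len(exp))
    sel = (d >= 2) & (d <= 60) & np.isfinite(exp) & (exp > 0)
    slope = np.polyfit(np.log(d[sel]), np.log(exp[sel]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_oe_of_expected_is_one(map_from_dense_factory):
    # a map that equals its own distance-decay expectation has O/E == 1
    n = 30
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(divide="ignore"):
        C = np.where(sep > 0, 100.0 / sep, 0.0)
    cmap = map_from_dense_factory(C)
    cmap.weights = np.ones(n)
    O = oe(cmap)
    off = ~np.eye(n, dtype=bool)
    assert np.allclose(O[off], 1.0)


def test_oe_grand_mean_near_one(synthetic_map):
    if synthetic_map.weights is None:
        ice_balance(synthetic_map)
    O = oe(synthetic_map)
    cis = synthetic_map.cis_mask() & ~np.eye(synthetic_map.n_bins, dtype=bool)
    vals = O[cis]
    assert np.nanmean(vals) == pytest.approx(1.0, abs=0.02)


def test_eigen_two_block_checkerboard_spectral_oracle(map_from_dense_factory):
    # two clean blocks: the leading eigenvector splits them exactly
    n = 20
    lab = np.array([1.0] * 10 + [-1.0] * 10)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    np.fill_diagonal(sep, np.inf)
    C = (50.0 / sep) * (1 + 0.4 * lab[:, None] * lab[None, :])
    cmap = map_from_dense_factory(C)
    cmap.weights = np.ones(n)
    track = eigen_compartments(cmap, orientation_reference=lab)
    assert not track.degenerate_chroms
    signs = np.sign(track.values)
    assert np.array_equal(signs, lab)


def test_eigen_uniform_map_degenerate(map_from_dense_factory):
    n = 15
    C = np.ones((n, n)) - np.eye(n)
    cmap = map_from_dense_factory(C)
    cmap.weights = np.ones(n)
    track = eigen_compartments(cmap, orientation_reference=np.ones(n))
    assert track.degenerate_chroms == ("chr1",)
    assert np.isnan(track.values).all()


def test_eigen_recovers_planted_track(synthetic_map, truth_with_loops):
    if synthetic_map.weights is None:
        ice_balance(synthetic_map)
    ref = truth_with_loops.compartment_track()
    track = eigen_compartments(synthetic_map, ref)
    ok = np.isfinite(track.values) & np.isfinite(ref)
    r = np.corrcoef(track.values[ok], ref[ok])[0, 1]
    assert r > 0.9


def test_saddle_planted_checkerboard_strength():
    """O/E = 1 +- 0.2 checkerboard gives corner strength (1.2/0.8)^2 = 2.25.

    The compartment track is estimated on an independent replicate: ranking
    bins by an eigenvector from the same map would select on noise and
    inflate the corners.
    """
    truth = SyntheticTruth(s=0.2)
    vals = []
    for seed in range(4):
        ref_map = synth_contact_map(truth, depth=4e6, replicate_seed=200 + seed)
        ice_balance(ref_map)
        track = eigen_compartments(ref_map, truth.compartment_track())
        cmap = synth_contact_map(truth, depth=4e6, replicate_seed=100 + seed)
        ice_balance(cmap)
        prof = saddle(cmap, track.values, n_quantiles=10, scope="cis")
        vals.append(compartment_strength(prof, corner_fraction=0.2))
    assert np.mean(vals) == pytest.approx(2.25, abs=0.1)


def test_saddle_shuffled_track_is_null(synthetic_map, truth_with_loops):
    if synthetic_map.weights is None:
        ice_balance(synthetic_map)
    e1 = eigen_compartments(
        synthetic_map, truth_with_loops.compartment_track()
    ).values
    rng = np.random.default_rng(0)
    track = rng.permutation(e1)
    prof = saddle(synthetic_map, track, n_quantiles=10, scope="cis")
    assert compartment_strength(prof) == pytest.approx(1.0, abs=0.15)


def test_saddle_null_amplitude_strength_one():
    """A generator map with no planted compartments has strength ~ 1."""
    truth = SyntheticTruth(s=0.0)
    cmap = synth_contact_map(truth, depth=3e6, replicate_seed=17)
    ice_balance(cmap)
    track = eigen_compartments(cmap, truth.compartment_track())
    prof = saddle(cmap, track.values, n_quantiles=10, scope="cis")
    assert compartment_strength(prof) == pytest.approx(1.0, abs=0.15)


def test_saddle_strength_monotone_in_amplitude():
    strengths = []
    for s in (0.1, 0.2, 0.3):
        truth = SyntheticTruth(s=s)
        cmap = synth_contact_map(truth, depth=3e6, replicate_seed=42)
        ice_balance(cmap)
        track = eigen_compartments(cmap, truth.compartment_track())
        prof = saddle(cmap, track.values, n_quantiles=10, scope="cis")
        strengths.append(compartment_strength(prof))
    assert strengths[0] < strengths[1] < strengths[2]


def test_saddle_profile_grand_mean_near_one(synthetic_map, truth_with_loops):
    if synthetic_map.weights is None:
        ice_balance(synthetic_map)
    track = eigen_compartments(synthetic_map, truth_with_loops.compartment_track())
    prof = saddle(synthetic_map, track.values, n_quantiles=10, scope="cis")
    assert np.nanmean(prof.profile) == pytest.approx(1.0, abs=0.05)


def test_saddle_rejects_too_many_quantiles(synthetic_map, truth_with_loops):
    if synthetic_map.weights is None:
        ice_balance(synthetic_map)
    with pytest.raises(ValueError, match="quantiles"):
        saddle(
            synthetic_map,
            truth_with_loops.compartment_track(),
            n_quantiles=synthetic_map.n_bins + 1,
        )


class TestMatchCisDepth:
    def _two_maps(self):
        truth = SyntheticTruth(s=0.1)
        m1 = synth_contact_map(truth, depth=1e5, replicate_seed=1)
        m2 = synth_contact_map(truth, depth=2e5, replicate_seed=2)
        return m1, m2

    def test_thinned_to_minimum_exactly(self):
        m1, m2 = self._two_maps()
        t1, t2 = m1.cis_total(), m2.cis_total()
        out = match_cis_depth([m1, m2], seed=0)
        assert out[0].cis_total() == t1  # minimum map untouched
        assert out[1].cis_total() == min(t1, t2)
        assert t2 > t1

    def test_equal_totals_unchanged(self):
        m1, _ = self._two_maps()
        out = match_cis_depth([m1, m1], seed=0)
        assert out[0] is m1 and out[1] is m1

    def test_deterministic(self):
        m1, m2 = self._two_maps()
        a = match_cis_depth([m1, m2], seed=3)[1]
        b = match_cis_depth([m1, m2], seed=3)[1]
        pd.testing.assert_frame_equal(a.pixels, b.pixels)

    def test_zero_cis_rejected(self, map_from_dense_factory):
        empty = map_from_dense_factory(np.zeros((4, 4)))
        m1, _ = self._two_maps()
        with pytest.raises(ValueError, match="zero cis"):
            match_cis_depth([m1, empty], seed=0)


def test_map_roundtrips(tmp_path, synthetic_map):
    sio.write_cool(synthetic_map, tmp_path / "m.cool")
    back = sio.read_cool(tmp_path / "m.cool")
    pd.testing.assert_frame_equal(
        back.bins, synthetic_map.bins, check_dtype=False
    )
    assert np.array_equal(
        back.pixels["count"].to_numpy(), synthetic_map.pixels["count"].to_numpy()
    )
    sio.write_map_tsv(synthetic_map, tmp_path / "m")
    back2 = sio.read_map_tsv(tmp_path / "m")
    assert back2.resolution == synthetic_map.resolution
    assert np.array_equal(
        back2.pixels[["bin1_id", "bin2_id"]].to_numpy(),
        synthetic_map.pixels[["bin1_id", "bin2_id"]].to_numpy(),
    )


def test_bins_are_zero_based_half_open():
    bins = make_bins({"chrX": 55_000}, 20_000)
    assert bins.iloc[0]["start"] == 0
    assert bins.iloc[-1]["end"] == 55_000
    assert (bins["end"] - bins["start"]).iloc[:-1].eq(20_000).all()
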