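"""I/O, balancing, clipping, windowing and assembly contracts."""

import numpy as np
import pytest

from hicformer.hic_io import (BinnedTrack, ContactMap, assemble,
                              clip_normalize, kr_normalize, normalize_track,
                              read_contact_map, read_cool, read_track,
                              sample_windows, write_bedgraph, write_cool,
                              write_triplet, ChromosomeNotFoundError)
from hicformer.synthetic import SyntheticSpec, simulate_contact_map

from conftest import random_symmetric


def sinkhorn_oracle(m: np.ndarray, iters: int = 50_000,
                    tol: float = 1e-13) -> np.ndarray:
    """Independent alternating row/column scaling to doubly stochastic."""
    a = m.copy()
    for _ in range(iters):
        a = a / a.sum(axis=1, keepdims=True)
        a = a / a.sum(axis=0, keepdims=True)
        if np.abs(a.sum(axis=1) - 1).max() < tol:
            break
    return (a + a.T) / 2


# ---------------------------------------------------------------------------
# contact-map reading / writing
# ---------------------------------------------------------------------------

def test_triplet_symmetrization(tmp_path):
    p = tmp_path / "m.txt"
    p.write_text("0\t1\t5\n")
    cmap = read_contact_map(p, "chrT", n_bins=3)
    np.testing.assert_array_equal(cmap.matrix,
                                  [[0, 5, 0], [5, 0, 0], [0, 0, 0]])


def test_empty_triplet_declared_bins(tmp_path):
    p = tmp_path / "e.txt"
    p.write_text("")
    cmap = read_contact_map(p, "chrT", n_bins=4)
    np.testing.assert_array_equal(cmap.matrix, np.zeros((4, 4)))


def test_asymmetric_triplet_symmetrized_by_max_with_warning(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("0\t1\t5\n1\t0\t9\n")
    with pytest.warns(UserWarning, match="symmetriz"):
        cmap = read_contact_map(p, "chrT", n_bins=2)
    np.testing.assert_array_equal(cmap.matrix, [[0, 9], [9, 0]])


def test_triplet_round_trip(tmp_path):
    spec = SyntheticSpec(n_bins=40, tads=[(5, 20, 3.0)], seed=8,
                         total_reads=30_000)
    cmap = simulate_contact_map(spec)
    p = tmp_path / "rt.txt"
    write_triplet(cmap, p)
    back = read_contact_map(p, spec.chrom, n_bins=40)
    np.testing.assert_allclose(back.matrix, cmap.matrix)


def test_cool_round_trip_multi_chrom(tmp_path):
    m1 = simulate_contact_map(SyntheticSpec(n_bins=24, seed=1,
                                            total_reads=10_000, chrom="chr1"))
    m2 = simulate_contact_map(SyntheticSpec(n_bins=30, seed=2,
                                            total_reads=10_000, chrom="chr2"))
    p = tmp_path / "maps.cool"
    write_cool([m1, m2], p)
    b1 = read_cool(p, "chr1")
    b2 = read_cool(p, "chr2")
    np.testing.assert_allclose(b1.matrix, m1.matrix)
    np.testing.assert_allclose(b2.matrix, m2.matrix)
    assert b2.resolution == m2.resolution
    with pytest.raises(ChromosomeNotFoundError):
        read_cool(p, "chr9")


# ---------------------------------------------------------------------------
# KR balancing
# ---------------------------------------------------------------------------

def test_kr_2x2_equal_row_sums_matches_sinkhorn():
    cmap = ContactMap(np.array([[2.0, 1.0], [1.0, 2.0]]))
    out = kr_normalize(cmap).matrix
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)
    np.testing.assert_allclose(out, sinkhorn_oracle(cmap.matrix), atol=1e-6)


def test_kr_already_balanced_fixed_point():
    m = np.array([[0.5, 0.5], [0.5, 0.5]])
    out = kr_normalize(ContactMap(m)).matrix
    np.testing.assert_allclose(out, m, atol=1e-8)


def test_kr_zero_row_masked(rng):
    m = random_symmetric(rng, 6)
    m[3, :] = 0.0
    m[:, 3] = 0.0
    out = kr_normalize(ContactMap(m)).matrix
    assert np.all(out[3, :] == 0) and np.all(out[:, 3] == 0)
    live = [i for i in range(6) if i != 3]
    np.testing.assert_allclose(out[live].sum(axis=1), 1.0, atol=1e-8)
    # oracle: balance the nonzero submatrix independently
    sub = sinkhorn_oracle(m[np.ix_(live, live)])
    np.testing.assert_allclose(out[np.ix_(live, live)], sub, atol=1e-6)


def test_kr_matches_sinkhorn_on_random_matrices(rng):
    for n in (5, 16, 40):
        m = random_symmetric(rng, n)
        out = kr_normalize(ContactMap(m)).matrix
        rs = out.sum(axis=1)
        assert np.abs(rs - rs.mean()).max() / rs.mean() < 1e-6
        np.testing.assert_allclose(out, sinkhorn_oracle(m), atol=1e-6)


# ---------------------------------------------------------------------------
# clip normalization
# ---------------------------------------------------------------------------

def test_clip_percentile_100_divides_by_max(rng):
    m = random_symmetric(rng, 12)
    out = clip_normalize(ContactMap(m), percentile=100).matrix
    np.testing.assert_allclose(out, m / m.max())


def test_clip_outlier_maps_to_one_order_preserved(rng):
    m = random_symmetric(rng, 30)
    m[2, 25] = m[25, 2] = 1e6
    out = clip_normalize(ContactMap(m), percentile=99.0).matrix
    assert out[2, 25] == 1.0
    assert out.max() == 1.0
    # quantile oracle: cutoff is the 99th percentile of nonzero band entries
    i, j = np.triu_indices(30)
    vals = m[i, j]
    cutoff = np.percentile(vals[vals > 0], 99.0)
    below = m < cutoff
    np.testing.assert_allclose(out[below], m[below] / cutoff)


def test_clip_constant_matrix_all_ones():
    m = np.full((8, 8), 3.0)
    out = clip_normalize(ContactMap(m)).matrix
    np.testing.assert_allclose(out, 1.0)


def test_clip_all_zero_warns_and_returns_unchanged():
    with pytest.warns(UserWarning):
        out = clip_normalize(ContactMap(np.zeros((5, 5))))
    np.testing.assert_array_equal(out.matrix, np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# windows and assembly
# ---------------------------------------------------------------------------

def test_window_starts_include_right_anchor(rng):
    cmap = ContactMap(random_symmetric(rng, 316))
    ws = sample_windows(cmap, [], size=256, stride_bins=30)
    assert [w.start_bin for w in ws] == [0, 30, 60]
    cmap2 = ContactMap(random_symmetric(rng, 300))
    ws2 = sample_windows(cmap2, [], size=256, stride_bins=30)
    assert [w.start_bin for w in ws2] == [0, 30, 44]


def test_single_window_when_exact_size(rng):
    cmap = ContactMap(random_symmetric(rng, 256))
    ws = sample_windows(cmap, [], size=256, stride_bins=30)
    assert len(ws) == 1 and ws[0].start_bin == 0


def test_short_chromosome_zero_padded_flagged(rng):
    cmap = ContactMap(random_symmetric(rng, 10))
    track = BinnedTrack(np.ones(10), assay_name="x")
    ws = sample_windows(cmap, [track], size=32, stride_bins=8)
    assert len(ws) == 1 and ws[0].padded
    assert ws[0].submatrix.shape == (32, 32)
    assert np.all(ws[0].submatrix[10:, :] == 0)
    assert len(ws[0].track_slices["x"]) == 32


def test_track_slices_have_window_length(rng):
    cmap = ContactMap(random_symmetric(rng, 80))
    tracks = [BinnedTrack(rng.uniform(size=80), assay_name=f"t{i}")
              for i in range(3)]
    ws = sample_windows(cmap, tracks, size=32, stride_bins=16)
    for w in ws:
        assert all(len(v) == 32 for v in w.track_slices.values())


def test_assemble_identity_reconstructs_band(rng):
    # pass-through predictions must reconstruct the diagonal band exactly
    cmap = ContactMap(random_symmetric(rng, 100))
    ws = sample_windows(cmap, [], size=32, stride_bins=8)
    out = assemble([(w, w.submatrix) for w in ws], 100).matrix
    covered = np.zeros((100, 100), dtype=bool)
    for w in ws:
        covered[w.start_bin:w.start_bin + 32, w.start_bin:w.start_bin + 32] \
            = True
    np.testing.assert_allclose(out[covered], cmap.matrix[covered],
                               atol=1e-12)
    assert np.all(out[~covered] == 0)


def test_assemble_constant_and_mean(rng):
    cmap = ContactMap(random_symmetric(rng, 60))
    ws = sample_windows(cmap, [], size=32, stride_bins=16)
    out = assemble([(w, np.full((32, 32), 0.7)) for w in ws], 60).matrix
    covered = out > 0
    np.testing.assert_allclose(out[covered], 0.7)
    # two overlapping windows, predictions 0 and 1 -> shared entries 0.5
    two = [ws[0], ws[1]]
    preds = [np.zeros((32, 32)), np.ones((32, 32))]
    out2 = assemble(list(zip(two, preds)), 60).matrix
    shared = np.zeros((60, 60), dtype=bool)
    shared[16:32, 16:32] = True
    np.testing.assert_allclose(out2[shared], 0.5)


def test_assemble_matches_coverage_count_oracle(rng):
    cmap = ContactMap(random_symmetric(rng, 90))
    ws = sample_windows(cmap, [], size=32, stride_bins=8)
    preds = [rng.uniform(size=(32, 32)) for _ in ws]
    preds = [(p + p.T) / 2 for p in preds]
    out = assemble(list(zip(ws, preds)), 90).matrix
    acc = np.zeros((90, 90))
    cov = np.zeros((90, 90))
    for w, p in zip(ws, preds):
        s = w.start_bin
        acc[s:s + 32, s:s + 32] += p
        cov[s:s + 32, s:s + 32] += 1
    expected = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    np.testing.assert_allclose(out, (expected + expected.T) / 2, atol=1e-12)


def test_assemble_rejects_inconsistent_sizes(rng):
    cmap = ContactMap(random_symmetric(rng, 64))
    ws = sample_windows(cmap, [], size=32, stride_bins=32)
    with pytest.raises(ValueError):
        assemble([(ws[0], np.zeros((16, 16)))], 64)


# ---------------------------------------------------------------------------
# 1-D tracks
# ---------------------------------------------------------------------------

def test_bedgraph_full_bin_value(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chrT\t0\t10000\t7\n")
    track = read_track(p, "chrT", resolution=10_000, n_bins=2)
    assert track.values[0] == 7.0
    assert track.values[1] == 0.0


def test_bedgraph_straddling_interval_coverage_weighted(tmp_path):
    # one interval covering [5000, 15000) at 4 plus [15000, 20000) at 8:
    # bin0 mean over covered bases = 4; bin1 = (4*5000 + 8*5000)/10000 = 6
    p = tmp_path / "t.bedgraph"
    p.write_text("chrT\t5000\t15000\t4\nchrT\t15000\t20000\t8\n")
    track = read_track(p, "chrT", resolution=10_000, n_bins=2)
    assert track.values[0] == pytest.approx(4.0)
    assert track.values[1] == pytest.approx(6.0)


def test_bedgraph_missing_chrom(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chrA\t0\t100\t1\n")
    with pytest.raises(ChromosomeNotFoundError):
        read_track(p, "chrB", resolution=10_000)
    with pytest.warns(UserWarning):
        track = read_track(p, "chrB", resolution=10_000, n_bins=3)
    np.testing.assert_array_equal(track.values, np.zeros(3))


def test_bedgraph_round_trip(tmp_path, rng):
    t = BinnedTrack(np.round(rng.uniform(0, 5, 20), 3), chrom="chrT",
                    assay_name="CTCF")
    p = tmp_path / "w.bedgraph"
    write_bedgraph(t, p)
    back = read_track(p, "chrT", resolution=10_000, n_bins=20)
    np.testing.assert_allclose(back.values, t.values, rtol=1e-4)


def test_normalize_track_range():
    t = BinnedTrack(np.array([0.0, 1.0, 2.0, 100.0]))
    out = normalize_track(t, percentile=75)
    assert out.values.max() == 1.0
    assert out.values.min() == 0.0
    assert np.all(out.values <= 1.0)
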