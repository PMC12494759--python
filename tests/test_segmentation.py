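"""Mask refinement, path fitting, 4.8 um segmentation and clustering."""

import warnings

import numpy as np
import pytest

from voltdend.data import Movie
from voltdend.segmentation import (
    DendritePath,
    arc_segment_edges,
    cluster_segments,
    extract_traces,
    fit_dendrite_path,
    refine_mask,
    segment_path,
)


class TestRefineMask:
    def test_sigma_zero_is_normalize_cube(self):
        raw = np.zeros((8, 8))
        raw[3, 2:6] = 1.0
        raw[4, 3] = 0.5
        out = refine_mask(raw, sigma=0.0)
        assert out[3, 2] == 1.0
        assert out[4, 3] == pytest.approx(0.125)  # 0.5 cubed

    def test_single_pixel_gaussian_profile(self):
        raw = np.zeros((15, 15))
        raw[7, 7] = 1.0
        out = refine_mask(raw, sigma=1.0)
        assert out[7, 7] == pytest.approx(1.0)
        # analytic 2-D Gaussian oracle: cubed ratio at distance 1 and 2
        g1, g2 = np.exp(-0.5), np.exp(-2.0)
        assert out[7, 8] == pytest.approx(g1**3, rel=1e-3)
        assert out[7, 9] == pytest.approx(g2**3, rel=1e-3)
        assert out[7, 7] > out[7, 8] > out[7, 9] > out[7, 10]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            refine_mask(np.zeros((5, 5)))

    def test_support_within_dilated_input(self):
        raw = np.zeros((12, 30))
        raw[5, 4:26] = 1.0
        out = refine_mask(raw, sigma=1.0)
        rr, cc = np.nonzero(out > 1e-6)
        assert rr.min() >= 2 and rr.max() <= 8  # within ~3 sigma dilation


class TestPathFit:
    def test_exact_line_recovered_in_image_coordinates(self):
        # pixels exactly on y = 2 + 0.1 x (pixel size 1 um -> integer grid)
        mask = np.zeros((12, 90))
        x = np.arange(0, 90, 10)
        mask[np.round(2 + 0.1 * x).astype(int), x] = 1.0
        path = fit_dendrite_path(mask, pixel_size_um=1.0)
        coeffs = path.coeffs_xy
        assert coeffs is not None
        assert np.allclose(coeffs, [2.0, 0.1, 0.0, 0.0], atol=1e-6)

    def test_straight_band_arc_length(self):
        mask = np.zeros((12, 40))
        mask[5:8, 4:35] = 1.0  # 31 columns tall band = 24 um at 0.8 um/px
        path = fit_dendrite_path(mask, pixel_size_um=0.8)
        assert abs(path.arc_length_um - 24.0) / 24.0 < 0.02

    def test_noisy_cubic_band_median_deviation(self):
        # cubic band + weight noise at SNR 10; median max deviation <= 0.5 px
        coeffs = np.array([6.0, 0.2, -0.01, 0.0002])
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = np.zeros((20, 50))
            xs = np.arange(2, 48)
            ys = np.polynomial.polynomial.polyval(xs.astype(float), coeffs)
            for dx in (-1, 0, 1):
                rr = np.clip(np.round(ys).astype(int) + dx, 0, 19)
                mask[rr, xs] += 1.0
            mask *= 1 + rng.normal(0, 0.1, mask.shape)
            mask = np.clip(mask, 0, None)
            path = fit_dendrite_path(mask, pixel_size_um=1.0)
            pts, _ = path.sample(500)
            true_y = np.polynomial.polynomial.polyval(pts[:, 0], coeffs)
            devs.append(np.max(np.abs(pts[:, 1] - true_y)))
        assert np.median(devs) <= 0.5

    def test_isotropic_blob_raises(self):
        mask = np.zeros((30, 30))
        yy, xx = np.mgrid[:30, :30]
        mask[(yy - 15) ** 2 + (xx - 15) ** 2 <= 100] = 1.0
        with pytest.raises(ValueError, match="isotropic"):
            fit_dendrite_path(mask, pixel_size_um=1.0)

    def test_vertical_dendrite_is_fit(self):
        mask = np.zeros((40, 12))
        mask[4:36, 5:8] = 1.0
        path = fit_dendrite_path(mask, pixel_size_um=0.8)
        assert path.arc_length_um > 15


def straight_path(length_um: float) -> DendritePath:
    return DendritePath(
        origin_um=np.array([length_um / 2, 4.0]),
        axes=np.eye(2),
        coeffs=np.zeros(4),
        u_range=(-length_um / 2, length_um / 2),
        arc_length_um=length_um,
        pixel_size_um=0.8,
    )


class TestSegmentation:
    def test_24um_gives_exactly_five_segments(self):
        edges = arc_segment_edges(24.0, 4.8)
        assert len(edges) - 1 == 5
        assert np.allclose(np.diff(edges), 4.8)

    def test_10um_remainder_merged(self):
        edges = arc_segment_edges(10.0, 4.8)
        assert np.allclose(np.diff(edges), [4.8, 5.2])

    def test_large_remainder_kept(self):
        edges = arc_segment_edges(12.0, 4.8)  # remainder 2.4 = 50% -> own segment
        assert np.allclose(np.diff(edges), [4.8, 4.8, 2.4])

    def test_short_arc_raises(self):
        with pytest.raises(ValueError, match="arc length"):
            arc_segment_edges(2.0, 4.8)

    def test_straight_path_assignment_is_nearest_x_binning(self):
        path = straight_path(24.0)
        mask = np.zeros((10, 40))
        mask[4:7, 0:31] = 1.0
        segs = segment_path(path, mask)
        assert segs.n_segments == 5
        rr, cc = np.nonzero(mask)
        x_um = cc * 0.8 - (path.origin_um[0] + path.u_range[0])
        expected = np.clip((x_um // 4.8).astype(int), 0, 4)
        # boundary pixels (x exactly on a segment edge) may fall either way
        # from floating-point arc sampling; all others must bin by nearest x
        interior = np.abs(x_um / 4.8 - np.round(x_um / 4.8)) > 1e-3
        assert np.array_equal(segs.labels[rr, cc][interior], expected[interior])


class TestExtractTraces:
    def _movie(self, data):
        data = np.asarray(data, dtype=np.float32)
        return Movie(data=data, frame_rate=440.0, pixel_size_um=0.8,
                     frame_times=np.arange(data.shape[0]) / 440.0)

    def test_uniform_frames(self):
        path = straight_path(10.0)
        mask = np.zeros((10, 40))
        mask[4:6, 0:14] = 1.0
        segs = segment_path(path, mask)
        movie = self._movie(np.full((300, 10, 40), 7.0))
        tr = extract_traces(movie, segs)
        assert np.allclose(tr, 7.0)

    def test_gated_frames_become_nan(self):
        path = straight_path(10.0)
        mask = np.zeros((10, 40))
        mask[4:6, 0:14] = 1.0
        segs = segment_path(path, mask)
        movie = self._movie(np.ones((300, 10, 40)))
        gated = np.zeros(300, bool)
        gated[10:12] = True
        tr = extract_traces(movie, segs, gated_frames=gated)
        assert np.isnan(tr[:, 10]).all() and np.isfinite(tr[:, 20]).all()

    def test_matches_ground_truth_coupling(self, clean_movie):
        cfg, movie, daq, gt = clean_movie
        mask = gt.cell_weights[0]
        path = fit_dendrite_path(mask, cfg.pixel_size_um)
        segs = segment_path(path, mask)
        tr = extract_traces(movie, segs)
        # mask weights are binary, so every segment trace follows the same
        # coupled voltage up to its own per-segment IPSP factor (no LED here)
        v = gt.voltage[0]
        for s in range(segs.n_segments):
            w = segs.segment_weight_map(s).ravel()
            expected = gt.background + cfg.brightness * (1 - v)
            assert np.allclose(tr[s], expected, atol=2e-4 * cfg.brightness)


class TestClustering:
    def test_single_segment_single_cluster(self):
        rng = np.random.default_rng(0)
        clusters, excl = cluster_segments(rng.normal(size=(1, 400)), 440.0)
        assert len(clusters) == 1 and not excl

    def test_duplicate_trace_joins_twin(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        clusters, _ = cluster_segments(np.stack([a, b, a.copy()]), 440.0)
        for cl in clusters:
            ids = set(cl.segment_ids.tolist())
            if 0 in ids:
                assert 2 in ids
                assert 1 not in ids

    def test_constant_segment_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        traces = np.stack([rng.normal(size=400), np.full(400, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            clusters, excl = cluster_segments(traces, 440.0)
        assert excl == [1]

    def test_two_cell_movie_clusters_match_identity(self, two_cell_movie, pipeline_config):
        cfg, movie, daq, gt = two_cell_movie
        all_tr, owner = [], []
        for ci, mask in enumerate(gt.cell_weights):
            refined = refine_mask(mask, 1.0)
            path = fit_dendrite_path(refined, cfg.pixel_size_um)
            segs = segment_path(path, refined)
            all_tr.append(extract_traces(movie, segs))
            owner.extend([ci] * segs.n_segments)
        clusters, _ = cluster_segments(np.vstack(all_tr), cfg.frame_rate)
        assert len(clusters) == 2
        owner = np.asarray(owner)
        for cl in clusters:
            assert len(set(owner[cl.segment_ids])) == 1
        # permutation invariance: shuffled segment order gives the same partition
        pooled = np.vstack(all_tr)
        perm = np.random.default_rng(3).permutation(len(pooled))
        clusters_p, _ = cluster_segments(pooled[perm], cfg.frame_rate)
        parts = sorted(tuple(sorted(perm[c.segment_ids])) for c in clusters_p)
        parts0 = sorted(tuple(sorted(c.segment_ids)) for c in clusters)
        assert parts == parts0
        # within-cluster correlation exceeds between-cluster correlation
        for cl in clusters:
            iu = np.triu_indices(len(cl.segment_ids), k=1)
            assert cl.corr[iu].mean() > 0.5

    def test_short_traces_rejected(self):
        with pytest.raises(ValueError, match="200"):
            cluster_segments(np.zeros((2, 100)), 440.0)
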