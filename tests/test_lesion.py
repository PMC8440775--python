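from __future__ import annotations

import numpy as np
import pytest

from redica import (BoundaryConfig, LesionConfig, WindowSpec, build_window_chain,
                    classify_patch, cluster_spots, compute_boundaries,
                    extract_lesions, extract_lesions_multiscale,
                    is_lesion_boundary, select_center_window)
from redica.lesion import WindowOutOfBounds

from _oracles import naive_components, naive_dark_fraction, naive_select_center

CFG = LesionConfig()


def _blob_image(m=120, n=120, center=(60, 60), radius=6, bg=0.9, depth=0.85):
    rr, cc = np.mgrid[0:m, 0:n]
    cov = np.clip(radius + 0.5 - np.hypot(rr - center[0], cc - center[1]), 0, 1)
    return np.clip(bg - depth * cov, 0.0, 1.0)


def _band_image(m=160, n=160, width=10, bg=0.9, depth=0.85):
    """Dark band at 45 degrees (along the main anti-diagonal direction)."""
    rr, cc = np.mgrid[0:m, 0:n]
    dist = np.abs(rr + cc - m) / np.sqrt(2)
    cov = np.clip(width / 2 + 0.5 - dist, 0, 1)
    return np.clip(bg - depth * cov, 0.0, 1.0)


class TestClassifyPatch:
    @pytest.mark.parametrize(
        "n_dark, expected",
        [(75, "dark"), (30, "light"), (50, "neither")],
    )
    def test_threshold_rule(self, as_pre, n_dark, expected):
        x = np.full((10, 10), 0.9)
        x.flat[:n_dark] = 0.1
        img = as_pre(x)
        lab = classify_patch(img, WindowSpec(0, 0, 10), CFG)
        assert lab.dark_fraction == pytest.approx(n_dark / 100)
        assert lab.label == expected

    def test_matches_naive_fraction(self, as_pre, random_images):
        img = as_pre(random_images[0])
        cfg = LesionConfig(t_dp=0.5, d_0=8)
        lab = classify_patch(img, WindowSpec(3, 5, 8), cfg)
        want = naive_dark_fraction(random_images[0], 3, 5, 8, 0.5)
        assert lab.dark_fraction == pytest.approx(want, abs=1e-12)

    def test_out_of_bounds_raises(self, as_pre):
        img = as_pre(np.zeros((12, 12)))
        with pytest.raises(WindowOutOfBounds):
            classify_patch(img, WindowSpec(5, 5, 10), CFG)


class TestSelectCenterWindow:
    def test_dark_below_picks_below_candidate(self, as_pre):
        x = np.full((40, 40), 0.9)
        x[20:, :] = 0.1  # dark strictly below row 20
        img = as_pre(x)
        w = select_center_window(img, 20, 20, d_0=10)
        # the three "below" candidates tie on the minimum; the first listed
        # below candidate (below-left) wins
        assert w.top_row == 20 and w.left_col == 10

    def test_constant_image_tie_break_above_left(self, as_pre):
        img = as_pre(np.full((30, 30), 0.5))
        w = select_center_window(img, 15, 15, d_0=10)
        assert (w.top_row, w.left_col) == (5, 5)

    def test_minimum_against_naive(self, as_pre, random_images):
        x = random_images[1]
        img = as_pre(x)
        w = select_center_window(img, 16, 16, d_0=10)
        (top, left), best_mean = naive_select_center(x, 16, 16, 10)
        assert (w.top_row, w.left_col) == (top, left)
        got_mean = x[w.top_row:w.top_row + 10, w.left_col:w.left_col + 10].mean()
        assert got_mean == pytest.approx(best_mean, abs=1e-12)

    def test_near_border_raises(self, as_pre):
        img = as_pre(np.zeros((30, 30)))
        with pytest.raises(WindowOutOfBounds):
            select_center_window(img, 5, 15, d_0=10)


class TestWindowChain:
    def test_direction_zero_shifts_columns(self):
        center = WindowSpec(50, 50, 10)
        chain = build_window_chain(center, 0.0, LesionConfig(d_0=10))
        assert [(w.top_row, w.left_col) for w in chain] == \
            [(50, 40), (50, 50), (50, 60)]

    def test_forty_five_degrees(self):
        center = WindowSpec(50, 50, 10)
        chain = build_window_chain(center, 45.0, LesionConfig(d_0=10))
        by_k = {w.k: (w.top_row, w.left_col) for w in chain}
        assert by_k[1] == (40, 60)
        assert by_k[-1] == (60, 40)

    def test_one_thirty_five_degrees(self):
        # tan(135) = -1: the lateral offset flips sign relative to 45 degrees
        center = WindowSpec(50, 50, 10)
        chain = build_window_chain(center, 135.0, LesionConfig(d_0=10))
        by_k = {w.k: (w.top_row, w.left_col) for w in chain}
        assert by_k[1] == (40, 60)

    def test_k_zero_is_center_for_every_theta(self):
        center = WindowSpec(33, 47, 10)
        for theta in (0.0, 30.0, 45.0, 60.0, 120.0, 135.0, 150.0):
            chain = build_window_chain(center, theta, CFG)
            w0 = next(w for w in chain if w.k == 0)
            assert (w0.top_row, w0.left_col) == (33, 47)

    def test_theta_ninety_rejected(self):
        with pytest.raises(ValueError, match="90"):
            build_window_chain(WindowSpec(50, 50, 10), 90.0, CFG)

    def test_floor_of_signed_product(self):
        # tan(30) = 0.5773...: k=+1 floors to +5, k=-1 floors to -6
        chain = build_window_chain(WindowSpec(50, 50, 10), 30.0,
                                   LesionConfig(d_0=10))
        by_k = {w.k: w.left_col for w in chain}
        assert by_k[1] == 55 and by_k[-1] == 44


class TestLesionDecision:
    def test_isolated_blob_accepted(self, as_pre):
        x = _blob_image(radius=6)
        img = as_pre(x)
        bset = compute_boundaries(img, BoundaryConfig(), use_fov=False)
        hits = [p for p in bset.p
                if is_lesion_boundary(img, p, (p in bset.p1, p in bset.p2))[0]]
        assert hits, "no boundary pixel of an isolated blob was accepted"
        for (i, j) in hits:
            assert np.hypot(i - 60, j - 60) <= 6 + 10

    def test_diagonal_band_rejected(self, as_pre):
        x = _band_image(width=10)
        img = as_pre(x)
        bset = compute_boundaries(img, BoundaryConfig(), use_fov=False)
        assert len(bset.p) > 0
        for p in bset.p:
            ok, diag = is_lesion_boundary(img, p, (p in bset.p1, p in bset.p2))
            assert not ok, f"vessel-band pixel {p} accepted: {diag}"

    def test_light_center_rejected(self, as_pre):
        img = as_pre(np.full((60, 60), 0.9))
        ok, diag = is_lesion_boundary(img, (30, 30), (True, False))
        assert not ok and diag["reason"] == "center_not_dark"

    def test_flank_off_image_rejected(self, as_pre):
        # dark blob close to the border: center window is dark but a
        # flanking window leaves the image
        x = _blob_image(m=44, n=44, center=(14, 14), radius=6)
        img = as_pre(x)
        ok, diag = is_lesion_boundary(img, (19, 14), (True, True))
        assert not ok
        assert diag["reason"] in ("flank_off_image", "center_not_dark",
                                  "flank_not_light")


class TestExtractLesions:
    def test_empty_boundaries(self, as_pre):
        from redica.boundary import BoundarySet
        img = as_pre(np.full((50, 50), 0.5))
        res = extract_lesions(img, BoundarySet(frozenset(), frozenset()))
        assert len(res) == 0

    def test_subset_of_boundary_set(self, as_pre):
        x = _blob_image()
        img = as_pre(x)
        bset = compute_boundaries(img, use_fov=False)
        res = extract_lesions(img, bset)
        assert res.pixels <= bset.p

    def test_blob_found_vessel_clean(self, as_pre):
        x = np.minimum(_blob_image(m=200, n=200, center=(40, 60), radius=6),
                       _band_image(m=200, n=200, width=8))
        img = as_pre(x)
        bset = compute_boundaries(img, use_fov=False)
        res = extract_lesions_multiscale(img, bset, d_0_scales=(10, 16, 22))
        assert res.pixels, "blob missed"
        for (i, j) in res.pixels:
            assert np.hypot(i - 40, j - 60) <= 6 + 22, \
                f"lesion pixel {(i, j)} far from the blob"

    def test_accepted_diagnostics_show_dark_center_light_flanks(self, as_pre):
        img = as_pre(_blob_image())
        bset = compute_boundaries(img, use_fov=False)
        res = extract_lesions(img, bset)
        assert res.pixels
        for p in res.pixels:
            diag = res.records[p]
            assert diag["center_dark_fraction"] > CFG.t_d
            assert all(lab == "light" for _, lab in diag["flanks"].values())

    def test_raising_td_never_enlarges(self, as_pre):
        img = as_pre(_blob_image())
        bset = compute_boundaries(img, use_fov=False)
        sizes = [len(extract_lesions(img, bset, CFG.replace(t_d=td)))
                 for td in (0.5, 0.7, 0.9)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_lowering_tl_never_enlarges(self, as_pre):
        img = as_pre(_blob_image())
        bset = compute_boundaries(img, use_fov=False)
        sizes = [len(extract_lesions(img, bset, CFG.replace(t_l=tl)))
                 for tl in (0.4, 0.2, 0.05)]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestClusterSpots:
    def test_two_close_pixels_one_spot(self):
        assert len(cluster_spots([(0, 0), (2, 0)], 10)) == 1

    def test_two_far_pixels_two_spots(self):
        spots = cluster_spots([(0, 0), (30, 0)], 10)
        assert len(spots) == 2

    def test_component_count_matches_naive_union_find(self, rng):
        for _ in range(5):
            pts = {(int(r), int(c))
                   for r, c in rng.integers(0, 80, size=(60, 2))}
            for radius in (3, 7):
                got = cluster_spots(pts, radius)
                assert len(got) == naive_components(pts, radius)

    def test_spot_geometry(self):
        (spot,) = cluster_spots([(5, 5), (5, 7), (7, 5)], 5)
        assert spot.n_pixels == 3
        assert spot.bbox == (5, 5, 7, 7)
        assert spot.centroid == pytest.approx((17 / 3, 17 / 3))
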