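import numpy as np
import pytest

from condenscan.imaging_coloc import (
    PunctaImage,
    coloc_puncta,
    detect_puncta,
    foci_count_per_cell,
    manders_coefficients,
    nearest_puncta_distance,
    puncta_positive_fraction,
)
from condenscan.synthetic_data import SimulationConfig, simulate_images


def gaussian_spot_image(centers, shape=(128, 128), sigma=2.0, peak=100.0,
                        background=1.0, pixel_size=0.1, channel="A"):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    for cy, cx in centers:
        img += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return PunctaImage({channel: img}, pixel_size=pixel_size)


class TestDetectPuncta:
    def test_single_spot_centroid_recovered(self):
        img = gaussian_spot_image([(40.0, 60.0)])
        ps = detect_puncta(img, "A")
        assert len(ps) == 1
        cy, cx = ps.puncta[0].centroid_px
        assert abs(cy - 40.0) < 0.5 and abs(cx - 60.0) < 0.5

    def test_blank_image_mean_k_sd_empty(self):
        img = PunctaImage({"A": np.zeros((64, 64))})
        ps = detect_puncta(img, "A", method="mean_plus_k_sd")
        assert len(ps) == 0

    def test_constant_image_otsu_is_error(self):
        img = PunctaImage({"A": np.ones((64, 64))})
        with pytest.raises(ValueError, match="constant"):
            detect_puncta(img, "A", method="otsu")

    def test_planted_spots_all_recovered(self):
        cfg = SimulationConfig(seed=0)
        img, truth = simulate_images(cfg, channels=("A",), n_puncta=10)
        ps = detect_puncta(img, "A")
        assert len(ps) == 10
        det = ps.centroids(physical=False)
        for _, row in truth.iterrows():
            d = np.sqrt(((det - [row.y_px, row.x_px]) ** 2).sum(axis=1)).min()
            assert d < 1.0

    def test_min_area_filters_small_components(self):
        arr = np.zeros((64, 64))
        arr[10:12, 10:12] = 50.0  # 4-pixel component
        arr[40:43, 40:43] = 50.0  # 9-pixel component
        img = PunctaImage({"A": arr})
        assert len(detect_puncta(img, "A", method="mean_plus_k_sd",
                                 min_area=5)) == 1
        assert len(detect_puncta(img, "A", method="mean_plus_k_sd",
                                 min_area=4)) == 2


class TestColocPairing:
    def test_identical_sets_all_paired_at_zero(self):
        img = gaussian_spot_image([(20.0, 20.0), (80.0, 80.0)])
        ps = detect_puncta(img, "A")
        pairs = coloc_puncta(ps, ps, max_centroid_dist=0.5)
        assert len(pairs) == 2
        assert all(d == 0.0 for _, _, d in pairs)

    def test_far_sets_unpaired(self):
        a = detect_puncta(gaussian_spot_image([(20.0, 20.0)]), "A")
        b = detect_puncta(gaussian_spot_image([(100.0, 100.0)]), "A")
        assert coloc_puncta(a, b, max_centroid_dist=0.5) == []

    def test_matches_optimal_matching_on_small_sets(self, rng):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        cap = 1.0
        for _ in range(30):
            # well-separated anchor positions: each punctum has at most one
            # plausible partner, where greedy pairing is provably optimal
            grid = rng.choice(100, size=10, replace=False)
            anchors = np.stack([grid // 10 * 5.0, grid % 10 * 5.0], axis=1)
            na = int(rng.integers(1, 10))
            nb = int(rng.integers(1, 10))
            ca = anchors[:na]
            cb = anchors[:nb] + rng.uniform(-0.3, 0.3, size=(nb, 2))
            pairs = coloc_puncta(_fake_set(ca), _fake_set(cb),
                                 max_centroid_dist=cap)
            adj = (np.sqrt(((ca[:, None] - cb[None]) ** 2).sum(-1)) <= cap)
            matching = maximum_bipartite_matching(
                csr_matrix(adj.astype(int)), perm_type="column"
            )
            best = int((matching >= 0).sum())
            assert len(pairs) == best


def _fake_set(centroids):
    from condenscan.imaging_coloc import PunctaSet, Punctum

    puncta = [
        Punctum(i + 1, tuple(c), tuple(c), 5, {})
        for i, c in enumerate(centroids)
    ]
    return PunctaSet(puncta, np.zeros((16, 16), dtype=int), "A", np.ones(2))


class TestPositiveFraction:
    def test_uniform_channel_no_positives(self):
        img = gaussian_spot_image([(30.0, 30.0)])
        img.channels["B"] = np.ones_like(img.channels["A"])
        ps = detect_puncta(img, "A")
        frac, flags = puncta_positive_fraction(ps, img, "B")
        assert frac == 0.0

    def test_hotspots_give_full_fraction(self):
        img = gaussian_spot_image([(30.0, 30.0), (90.0, 90.0)])
        b = np.ones_like(img.channels["A"])
        b[25:35, 25:35] = 10.0
        b[85:95, 85:95] = 10.0
        img.channels["B"] = b
        ps = detect_puncta(img, "A")
        frac, _ = puncta_positive_fraction(ps, img, "B")
        assert frac == 1.0

    def test_planted_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(
            seed=0, image_shape=(1024, 1024), image_noise_sd=0.5
        )
        img, truth = simulate_images(
            cfg, channels=("A", "B"), n_puncta=200,
            coloc_fractions={"B": 0.5},
        )
        ps = detect_puncta(img, "A")
        frac, _ = puncta_positive_fraction(ps, img, "B")
        # binomial 95% CI around 0.5 at n=200 is about +/- 0.07
        assert abs(frac - 0.5) < 0.07

    def test_empty_set_is_error(self):
        img = gaussian_spot_image([(30.0, 30.0)])
        ps = detect_puncta(PunctaImage({"A": np.zeros((32, 32))}), "A",
                           method="mean_plus_k_sd")
        with pytest.raises(ValueError):
            puncta_positive_fraction(ps, img, "A")


class TestManders:
    def test_identical_channels_give_one(self, rng):
        arr = rng.random((32, 32)) * 10
        img = PunctaImage({"A": arr, "B": arr.copy()})
        res = manders_coefficients(img, "A", "B")
        assert res.m1 == pytest.approx(1.0)
        assert res.m2 == pytest.approx(1.0)

    def test_disjoint_channels_give_zero(self):
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        a[:16] = 5.0
        b[16:] = 5.0
        a[0, 0] = b[31, 31] = 0.1  # keep Otsu defined
        img = PunctaImage({"A": a, "B": b})
        res = manders_coefficients(img, "A", "B")
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            a = rng.random((16, 16)) * 10
            b = rng.random((16, 16)) * 10
            t_a, t_b = float(rng.uniform(2, 8)), float(rng.uniform(2, 8))
            img = PunctaImage({"A": a, "B": b})
            res = manders_coefficients(img, "A", "B", thresholds=(t_a, t_b))
            num1 = den1 = num2 = den2 = 0.0
            for i in range(16):
                for j in range(16):
                    if a[i, j] > t_a:
                        den1 += a[i, j]
                        if b[i, j] > t_b:
                            num1 += a[i, j]
                    if b[i, j] > t_b:
                        den2 += b[i, j]
                        if a[i, j] > t_a:
                            num2 += b[i, j]
            assert abs(res.m1 - num1 / den1) < 1e-12
            assert abs(res.m2 - num2 / den2) < 1e-12

    def test_scale_invariance_with_scaled_thresholds(self, rng):
        a = rng.random((16, 16)) * 10
        b = rng.random((16, 16)) * 10
        img1 = PunctaImage({"A": a, "B": b})
        img2 = PunctaImage({"A": a * 7, "B": b})
        r1 = manders_coefficients(img1, "A", "B", thresholds=(3.0, 4.0))
        r2 = manders_coefficients(img2, "A", "B", thresholds=(21.0, 4.0))
        assert r1.m1 == pytest.approx(r2.m1)
        assert r1.m2 == pytest.approx(r2.m2)

    def test_zero_channel_is_error(self):
        img = PunctaImage({"A": np.zeros((8, 8)), "B": np.ones((8, 8))})
        with pytest.raises(ValueError):
            manders_coefficients(img, "A", "B")


class TestNearestDistance:
    def test_point_at_centroid_is_zero(self):
        img = gaussian_spot_image([(40.0, 60.0)])
        ps = detect_puncta(img, "A")
        d = nearest_puncta_distance([ps.puncta[0].centroid], ps)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five(self):
        ps = _fake_set(np.array([[0.0, 0.0]]))
        # a point 3-4 pixels away at pixel_size 0.1 -> 0.5 units
        d = nearest_puncta_distance([(0.3, 0.4)], ps)
        assert d[0] == pytest.approx(0.5)

    def test_matches_all_pairs_minimum(self, rng):
        centroids = rng.uniform(0, 10, size=(20, 2))
        ps = _fake_set(centroids)
        pts = rng.uniform(0, 10, size=(30, 2))
        d = nearest_puncta_distance(pts, ps)
        brute = np.sqrt(
            ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        np.testing.assert_allclose(d, brute, atol=1e-12)

    def test_translation_and_rotation_invariance(self, rng):
        centroids = rng.uniform(2, 8, size=(10, 2))
        pts = rng.uniform(2, 8, size=(15, 2))
        d0 = nearest_puncta_distance(pts, _fake_set(centroids))
        shift = np.array([1.3, -0.7])
        d1 = nearest_puncta_distance(pts + shift, _fake_set(centroids + shift))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        d2 = nearest_puncta_distance(pts @ rot.T, _fake_set(centroids @ rot.T))
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        np.testing.assert_allclose(d0, d2, atol=1e-9)

    def test_empty_puncta_is_error(self):
        empty = _fake_set(np.empty((0, 2)))
        with pytest.raises(ValueError, match="no reference"):
            nearest_puncta_distance([(0.0, 0.0)], empty)


class TestFociPerCell:
    def test_counts_per_cell(self):
        img = gaussian_spot_image(
            [(20.0, 20.0), (20.0, 40.0), (20.0, 60.0),
             (100.0, 20.0), (100.0, 40.0), (100.0, 60.0),
             (100.0, 80.0), (100.0, 100.0)]
        )
        top = np.zeros((128, 128), dtype=bool)
        top[:64] = True
        bottom = ~top
        out = foci_count_per_cell(img, "A", [top, bottom])
        assert out["counts"] == [3, 5]

    def test_blank_cell_counts_zero(self):
        img = gaussian_spot_image([(20.0, 20.0)])
        left = np.zeros((128, 128), dtype=bool)
        left[:, :64] = True
        right = ~left
        out = foci_count_per_cell(img, "A", [left, right])
        assert out["counts"] == [1, 0]

    def test_overlapping_masks_rejected(self):
        img = gaussian_spot_image([(20.0, 20.0)])
        m = np.ones((128, 128), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            foci_count_per_cell(img, "A", [m, m])
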