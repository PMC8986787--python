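"""Atlas construction: ensemble CAM, patch extraction, percentile, atlases."""

import numpy as np
import pytest

from psimlabel.atlas import (DistributionAtlas, _leave_self_out_fd,
                             build_distribution_atlas, build_patch_atlas,
                             ensemble_cam, extract_patches, patch_to_vector,
                             percentile)


def brute_force_ensemble_cam(cams, tau):
    """Direct pixelwise evaluation: per-member min-max normalize, unit-step
    threshold at tau, Hadamard, sum, linear rescale to peak 1."""
    def norm(m):
        lo, hi = m.min(), m.max()
        if hi > lo:
            return (m - lo) / (hi - lo)
        return np.ones_like(m) if hi > 0 else np.zeros_like(m)
    total = np.zeros_like(np.asarray(cams[0], dtype=float))
    for m in cams:
        nm = norm(np.asarray(m, dtype=float))
        for i in range(nm.shape[0]):
            for j in range(nm.shape[1]):
                u = 1.0 if nm[i, j] - tau >= 0 else 0.0
                total[i, j] += nm[i, j] * u
    return total / total.max() if total.max() > 0 else total


class TestEnsembleCAM:
    def test_single_map_tau_zero_is_minmax(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 6))
        out = ensemble_cam([m], tau=0.0)
        expected = (m - m.min()) / (m.max() - m.min())
        assert np.allclose(out.map, expected)

    def test_two_identical_maps_scale_invariant(self):
        m = np.random.default_rng(1).uniform(size=(5, 5))
        single = ensemble_cam([m], tau=0.0).map
        double = ensemble_cam([m, m], tau=0.0).map
        assert np.allclose(single, double)

    def test_disjoint_supports_union(self):
        a = np.zeros((4, 4)); a[0, 0] = 1.0; a[0, 1] = 0.9
        b = np.zeros((4, 4)); b[3, 3] = 1.0; b[3, 2] = 0.8
        out = ensemble_cam([a, b], tau=0.5).map
        support = set(map(tuple, np.argwhere(out > 0)))
        assert support == {(0, 0), (0, 1), (3, 3), (3, 2)}
        assert np.allclose(out, brute_force_ensemble_cam([a, b], 0.5))

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            s = rng.integers(1, 5)
            h, w = rng.integers(2, 9, size=2)
            cams = [rng.normal(size=(h, w)) for _ in range(s)]
            tau = float(rng.uniform(0, 0.9))
            out = ensemble_cam(cams, tau).map
            assert np.allclose(out, brute_force_ensemble_cam(cams, tau))

    def test_support_shrinks_as_tau_grows(self):
        rng = np.random.default_rng(3)
        cams = [rng.uniform(size=(8, 8)) for _ in range(3)]
        prev = None
        for tau in np.linspace(0, 1, 11):
            supp = set(map(tuple, np.argwhere(ensemble_cam(cams, tau).map > 0)))
            if prev is not None:
                assert supp <= prev
            prev = supp

    def test_all_zero_sum_stays_zero(self):
        out = ensemble_cam([np.zeros((4, 4))], tau=0.0)
        assert not out.map.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_cam([np.zeros((3, 3)), np.zeros((4, 4))], 0.1)


class TestPercentile:
    def test_hand_counted(self):
        assert percentile([0.2, 0.4, 0.6], 0.4) == pytest.approx(2 / 3)

    def test_boundaries(self):
        s = [0.1, 0.5, 0.9]
        assert percentile(s, 0.0) == 0.0
        assert percentile(s, 0.9) == 1.0
        assert percentile(s, 2.0) == 1.0

    def test_matches_bruteforce_count_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(1, 200)
            sample = np.sort(np.round(rng.uniform(size=n), 2))  # force ties
            v = float(rng.uniform(-0.1, 1.1))
            brute = sum(1 for x in sample if x <= v) / n
            assert percentile(sample, v) == brute

    def test_nondecreasing_over_sample_points(self):
        sample = np.sort(np.random.default_rng(5).uniform(size=30))
        vals = [percentile(sample, v) for v in sample]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 0.5)


class TestPatchToVector:
    def test_constant_region(self):
        img = np.full((40, 40), 0.5)
        v = patch_to_vector(img, (5, 5, 25, 25), D=16)
        assert np.allclose(v, 0.5)

    def test_exact_size_is_identity(self):
        img = np.random.default_rng(0).uniform(size=(40, 40))
        v = patch_to_vector(img, (3, 7, 3 + 4, 7 + 4), D=16)
        assert np.array_equal(v, img[3:7, 7:11].ravel())

    def test_matches_independent_resampler(self):
        from PIL import Image
        from scipy import ndimage
        img = ndimage.gaussian_filter(
            np.random.default_rng(1).uniform(size=(50, 60)), sigma=2.0)
        img = (img - img.min()) / (img.max() - img.min())
        bbox = (10, 5, 42, 51)
        v = patch_to_vector(img, bbox, D=1024).reshape(32, 32)
        crop = img[10:42, 5:51]
        pil = np.asarray(Image.fromarray((crop * 255).astype(np.uint8)).resize(
            (32, 32), Image.BILINEAR), dtype=float) / 255
        # PIL quantizes to uint8 and uses a slightly different edge
        # convention, so agreement is strong but not exact
        assert np.corrcoef(v.ravel(), pil.ravel())[0, 1] > 0.95
        assert np.abs(v - pil).max() < 0.2

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            patch_to_vector(np.zeros((20, 20)), (5, 5, 5, 10), D=16)

    def test_non_square_dimension_rejected(self):
        with pytest.raises(ValueError):
            patch_to_vector(np.zeros((20, 20)), (0, 0, 5, 5), D=15)


class TestExtractPatches:
    def test_blank_cam_yields_nothing(self):
        assert extract_patches(np.zeros((16, 16)), np.zeros((16, 16))) == []

    def test_single_disk_bbox_contains_disk(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disk = ((yy - 10) ** 2 + (xx - 20) ** 2 <= 16).astype(float)
        img = np.random.default_rng(0).uniform(size=(32, 32))
        patches = extract_patches(disk, img, D=16)
        assert len(patches) == 1
        r0, c0, r1, c1 = patches[0].bbox
        assert r0 <= 6 and r1 >= 15 and c0 <= 16 and c1 >= 25

    def test_two_disks_and_max_patches(self):
        cam = np.zeros((40, 40))
        cam[5:11, 5:11] = 1.0      # area 36
        cam[25:35, 25:35] = 1.0    # area 100
        img = np.random.default_rng(1).uniform(size=(40, 40))
        two = extract_patches(cam, img, max_patches=2, D=16)
        assert len(two) == 2
        one = extract_patches(cam, img, max_patches=1, D=16)
        assert len(one) == 1
        assert one[0].bbox == (25, 25, 35, 35)  # larger wins

    def test_equal_area_tie_breaks_topleft(self):
        cam = np.zeros((40, 40))
        cam[30:36, 2:8] = 1.0
        cam[2:8, 30:36] = 1.0
        img = np.random.default_rng(2).uniform(size=(40, 40))
        one = extract_patches(cam, img, max_patches=1, D=16)
        assert one[0].bbox == (2, 30, 8, 36)

    def test_components_match_scipy_labeling(self):
        from scipy import ndimage
        rng = np.random.default_rng(9)
        for _ in range(10):
            cam = (rng.uniform(size=(24, 24)) > 0.8).astype(float)
            img = rng.uniform(size=(24, 24))
            got = extract_patches(cam, img, max_patches=10_000,
                                  min_area_fraction=0.0, D=16)
            lab, n = ndimage.label(cam >= 0.5, structure=np.ones((3, 3)))
            assert len(got) == n


class _StubModel:
    """Deterministic classifier stub: probability = configured table."""

    def __init__(self, probs, n_labels):
        self._probs = np.asarray(probs, dtype=float)
        self.n_labels = n_labels

    def predict_proba(self, images):
        return self._probs

    def feature_maps(self, images):
        imgs = np.asarray(images)
        return imgs[:, None, ::4, ::4].astype(float)

    def class_weights(self, c):
        return np.ones(1)


class _StubEnsemble:
    def __init__(self, probs, n_labels):
        self.members = [_StubModel(probs, n_labels)]
        self.member_omegas = [1.0]
        self.n_labels = n_labels

    def predict_proba(self, images):
        return self.members[0].predict_proba(images)


class TestDistributionAtlas:
    def test_two_image_partition(self):
        probs = np.array([[0.9, 0.9], [0.1, 0.1]])
        ens = _StubEnsemble(probs, 1)
        import psimlabel as pl
        data = pl.LabeledImageSet(
            images=np.zeros((2, 16, 16), dtype=np.float32),
            true_labels=np.array([[1], [0]], dtype=np.int8),
            train_labels=np.array([[1], [0]], dtype=np.int8),
            view=np.ones(2, dtype=np.int8), ids=["a", "b"])
        atlas = build_distribution_atlas(ens, data)
        assert list(atlas.positive[0]) == [0.9]
        assert list(atlas.negative[0]) == [0.1]

    def test_ignore_cells_excluded_and_bruteforce_partition(self):
        rng = np.random.default_rng(4)
        n = 50
        probs = np.column_stack([rng.uniform(size=n), np.zeros(n)])
        labels = rng.choice([-1, 0, 1], size=n).astype(np.int8)
        import psimlabel as pl
        data = pl.LabeledImageSet(
            images=np.zeros((n, 16, 16), dtype=np.float32),
            true_labels=np.clip(labels, 0, 1)[:, None],
            train_labels=labels[:, None],
            view=np.ones(n, dtype=np.int8), ids=[f"i{k}" for k in range(n)])
        atlas = build_distribution_atlas(_StubEnsemble(probs, 1), data)
        brute_pos = sorted(probs[i, 0] for i in range(n) if labels[i] == 1)
        brute_neg = sorted(probs[i, 0] for i in range(n) if labels[i] == 0)
        assert np.allclose(atlas.positive[0], brute_pos)
        assert np.allclose(atlas.negative[0], brute_neg)

    def test_save_load_roundtrip(self, tmp_path):
        atlas = DistributionAtlas([np.array([0.2, 0.8])], [np.array([0.1])], ["a"])
        atlas.save(tmp_path / "da")
        back = DistributionAtlas.load(tmp_path / "da")
        assert np.array_equal(back.positive[0], atlas.positive[0])
        assert back.label_names == ["a"]


class TestFdReference:
    def test_three_points_k1_bruteforce(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        got = _leave_self_out_fd(pts, K=1)
        # nearest-other distances: 1 (0->1), 1 (1->0), 2 (2->1)
        assert np.allclose(got, [1.0, 1.0, 2.0])

    def test_k_clipped_to_n_minus_1(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        got = _leave_self_out_fd(pts, K=10)
        d01, d02, d12 = 2.0, 2.0, np.hypot(2, 2)
        brute = sorted([(d01 + d02) / 2, (d01 + d12) / 2, (d02 + d12) / 2])
        assert np.allclose(got, brute)


class TestBuildPatchAtlas:
    def _dataset(self, n=12):
        import psimlabel as pl
        cfg = pl.SynthConfig(image_height=32, image_width=32, n_labels=1,
                             finding_kind_per_label=("focal",),
                             prevalence_per_label=(0.5,), label_noise_rate=0.0,
                             rng_seed=13)
        return pl.generate_dataset(cfg, n)

    def test_no_qualifying_images_all_unavailable(self):
        data = self._dataset()
        probs = np.full((data.n_images, 1), 0.2)
        with pytest.warns(UserWarning):
            atlas = build_patch_atlas(_StubEnsemble(probs, 1), data,
                                      inclusion_threshold=0.9, K=2, tau=0.0,
                                      embedding_kind="projection", D=16)
        assert not atlas.available(0)

    def test_deterministic_under_seed(self):
        data = self._dataset()
        probs = np.random.default_rng(0).uniform(0.85, 1.0, size=(data.n_images, 1))
        kw = dict(inclusion_threshold=0.9, K=2, tau=0.1, embed_seed=3,
                  embedding_kind="projection", D=16)
        a = build_patch_atlas(_StubEnsemble(probs, 1), data, **kw)
        b = build_patch_atlas(_StubEnsemble(probs, 1), data, **kw)
        assert np.array_equal(a.coords[0], b.coords[0])
        assert np.array_equal(a.fd_reference[0], b.fd_reference[0])

    def test_fd_reference_matches_bruteforce_knn(self):
        data = self._dataset()
        probs = np.ones((data.n_images, 1))
        atlas = build_patch_atlas(_StubEnsemble(probs, 1), data,
                                  inclusion_threshold=0.9, K=3, tau=0.0,
                                  embedding_kind="projection", D=16)
        pts = atlas.coords[0]
        brute = []
        for i in range(len(pts)):
            d = sorted(np.hypot(*(pts[i] - pts[j])) for j in range(len(pts)) if j != i)
            brute.append(np.mean(d[:3]))
        assert np.allclose(atlas.fd_reference[0], sorted(brute))

    def test_save_load_roundtrip(self, tmp_path):
        data = self._dataset()
        probs = np.ones((data.n_images, 1))
        atlas = build_patch_atlas(_StubEnsemble(probs, 1), data,
                                  inclusion_threshold=0.9, K=2, tau=0.0,
                                  embedding_kind="projection", D=16)
        from psimlabel.atlas import PatchAtlas
        atlas.save(tmp_path / "pa")
        back = PatchAtlas.load(tmp_path / "pa")
        assert np.array_equal(back.coords[0], atlas.coords[0])
        assert np.array_equal(back.fd_reference[0], atlas.fd_reference[0])
        assert back.K == atlas.K and back.D == atlas.D
        q = np.stack([p.vector for p in atlas.patches[0][:2]])
        assert np.allclose(back.embedding.transform(q), atlas.embedding.transform(q))
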