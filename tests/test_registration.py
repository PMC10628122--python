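"""Keypoint matching, ratio filtering, robust homography estimation, and
patch extraction, validated against the synthetic generator's known
transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtustain.geometry import (
    apply_homography,
    corner_error,
    identity_homography,
    make_homography,
    normalize_homography,
)
from virtustain.registration import (
    HomographyRegistrar,
    InsufficientFeaturesError,
    KeypointMatch,
    PatchBox,
    RegistrationError,
    build_paired_dataset,
    detect_and_match,
    estimate_homography,
    lowe_ratio_filter,
    register_frames,
    warp_and_crop,
)
from virtustain.synthetic import cell_box, generate_donor_dataset, random_scene, render_scene


def _exact_matches(H, n=8, seed=0):
    rng = np.random.default_rng(seed)
    src = rng.uniform(10, 150, (n, 2))
    dst = apply_homography(H, src)
    return [
        KeypointMatch(tuple(s), tuple(d), dist_best=0.1, dist_second=0.9)
        for s, d in zip(src, dst)
    ]


class TestDetectAndMatch:
    def test_frame_against_itself_matches_in_place(self):
        render = render_scene(random_scene(0, homography="identity"))
        matches = lowe_ratio_filter(detect_and_match(render.bfi, render.bfi))
        assert len(matches) >= 20
        for m in matches:
            assert np.hypot(m.src_pt[0] - m.dst_pt[0], m.src_pt[1] - m.dst_pt[1]) < 0.5

    def test_pure_translation_median_displacement(self):
        render = render_scene(random_scene(1, homography="identity"))
        shifted = np.roll(render.bfi, 10, axis=1)  # tx = +10 px
        matches = lowe_ratio_filter(detect_and_match(shifted, render.bfi))
        disp = np.array([np.subtract(m.dst_pt, m.src_pt) for m in matches])
        med = np.median(disp, axis=0)
        assert med[0] == pytest.approx(10.0, abs=0.5)
        assert med[1] == pytest.approx(0.0, abs=0.5)

    def test_blank_frame_raises_named_error(self):
        blank = np.full((160, 160), 17, dtype=np.uint8)
        render = render_scene(random_scene(2))
        with pytest.raises(InsufficientFeaturesError, match="fluorescence"):
            detect_and_match(render.bfi, blank)

    def test_mixed_bit_depth_rejected(self):
        a = np.zeros((64, 64), dtype=np.uint8)
        b = np.zeros((64, 64), dtype=np.uint16)
        with pytest.raises(ValueError, match="bit depth"):
            detect_and_match(a, b)


class TestLoweRatioFilter:
    def test_keeps_confident_match(self):
        m = KeypointMatch((0, 0), (0, 0), dist_best=0.2, dist_second=0.9)
        assert lowe_ratio_filter([m], ratio=0.75) == [m]

    def test_drops_ambiguous_match(self):
        m = KeypointMatch((0, 0), (0, 0), dist_best=0.8, dist_second=0.9)
        assert lowe_ratio_filter([m], ratio=0.75) == []

    def test_empty_input(self):
        assert lowe_ratio_filter([], ratio=0.5) == []

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            lowe_ratio_filter([], ratio=1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    def test_subset_and_idempotent(self, seed, ratio):
        rng = np.random.default_rng(seed)
        matches = []
        for _ in range(20):
            d2 = rng.uniform(0.1, 1.0)
            matches.append(
                KeypointMatch(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 100, 2)),
                              dist_best=rng.uniform(0, d2), dist_second=d2)
            )
        once = lowe_ratio_filter(matches, ratio)
        assert all(m in matches for m in once)
        assert lowe_ratio_filter(once, ratio) == once


class TestEstimateHomography:
    def test_exact_recovery_from_eight_correspondences(self):
        H_true = make_homography(tx=5.0, ty=-3.0)
        H, inliers = estimate_homography(_exact_matches(H_true), min_inliers=4)
        assert corner_error(H, H_true, (160, 160)) < 1e-6
        assert inliers.all()

    def test_outliers_flagged_and_recovery_unaffected(self):
        H_true = make_homography(tx=5.0, ty=-3.0, theta_deg=2.0)
        good = _exact_matches(H_true, n=8, seed=1)
        rng = np.random.default_rng(9)
        bad = [
            KeypointMatch(tuple(rng.uniform(0, 160, 2)), tuple(rng.uniform(0, 160, 2)),
                          dist_best=0.1, dist_second=0.9)
            for _ in range(4)
        ]
        H, inliers = estimate_homography(good + bad, min_inliers=4, seed=3)
        assert corner_error(H, H_true, (160, 160)) < 1e-6
        assert inliers[: len(good)].all()
        assert not inliers[len(good):].any()

    def test_fewer_than_four_matches_rejected(self):
        H_true = make_homography(tx=1.0)
        with pytest.raises(RegistrationError, match=">= 4"):
            estimate_homography(_exact_matches(H_true, n=3))

    def test_min_inlier_floor_enforced(self):
        H_true = make_homography(tx=1.0)
        with pytest.raises(RegistrationError, match="inlier"):
            estimate_homography(_exact_matches(H_true, n=6), min_inliers=10)

    def test_result_is_normalized(self):
        H, _ = estimate_homography(_exact_matches(make_homography(tx=2.0)), min_inliers=4)
        assert H[2, 2] == pytest.approx(1.0)


class TestWarpAndCrop:
    def test_identity_full_frame_bit_exact(self, rng):
        frame = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        out = warp_and_crop(frame, identity_homography(), [(0, 0, 64, 64)], out_size=64)
        np.testing.assert_array_equal(out[0], frame)

    def test_constant_frame_stays_constant(self):
        frame = np.full((128, 128), 37, dtype=np.uint8)
        H = make_homography(tx=3.5, ty=-2.2, theta_deg=1.5)
        out = warp_and_crop(frame, H, [(32, 32, 96, 96)], out_size=32)
        np.testing.assert_array_equal(out[0], np.full((32, 32), 37, dtype=np.uint8))

    def test_warp_realigns_blob_centroids(self):
        spec = random_scene(21, bg_jitter=0, border_margin=24, n_cells=6)
        render = render_scene(spec)
        boxes = [cell_box(c) for c in spec.cells]
        side = boxes[0][2] - boxes[0][0]
        patches = warp_and_crop(render.dsdna, spec.homography_true, boxes,
                                out_size=max(side, 16))
        for patch, (r0, c0, r1, c1), cell in zip(patches, boxes, spec.cells):
            ref = render.ds_clean[r0:r1, c0:c1]
            if patch.shape != ref.shape:
                continue
            sig = np.clip(patch.astype(float) - spec.bg_level_ds, 0, None)
            rr, cc = np.mgrid[0 : sig.shape[0], 0 : sig.shape[1]]
            cy = np.average(rr, weights=sig)
            cx = np.average(cc, weights=sig)
            ry = np.average(rr, weights=ref + 1e-12)
            rx = np.average(cc, weights=ref + 1e-12)
            assert np.hypot(cy - ry, cx - rx) < 1.0

    def test_out_of_bounds_box_skipped_with_warning(self, caplog):
        frame = np.zeros((64, 64), dtype=np.uint8)
        patches, kept = warp_and_crop(
            frame, identity_homography(), [(0, 0, 32, 32), (40, 40, 80, 80)],
            out_size=16, return_kept=True,
        )
        assert kept == [0] and len(patches) == 1

    def test_roundtrip_correlation(self):
        render = render_scene(random_scene(8, homography="identity"))
        H = make_homography(tx=6.0, ty=-4.0, theta_deg=3.0, scale=1.02,
                            center=(80, 80))
        fwd = warp_and_crop(render.bfi, H, [(0, 0, 160, 160)], out_size=160)[0]
        back = warp_and_crop(fwd, np.linalg.inv(H), [(0, 0, 160, 160)], out_size=160)[0]
        inner = (slice(30, 130), slice(30, 130))  # exclude border fill
        c = np.corrcoef(render.bfi[inner].ravel(), back[inner].ravel())[0, 1]
        assert c > 0.98

    def test_small_out_size_rejected(self):
        with pytest.raises(ValueError):
            warp_and_crop(np.zeros((64, 64)), identity_homography(), [], out_size=8)


class TestRecoveryProperty:
    @pytest.mark.parametrize("seed", range(0, 20, 4))
    def test_random_projective_perturbations_recovered(self, seed):
        spec = random_scene(seed)
        render = render_scene(spec)
        res = register_frames(render.bfi, render.dsdna, seed=seed)
        assert corner_error(res.homography, spec.homography_true, spec.frame_size) < 1.0


class TestRegistrarEstimator:
    def test_fit_exposes_fitted_attributes(self):
        spec = random_scene(3)
        render = render_scene(spec)
        reg = HomographyRegistrar(seed=3).fit(render.dsdna, render.bfi)
        assert reg.homography_.shape == (3, 3)
        assert reg.n_inliers_ >= 8
        assert corner_error(reg.homography_, spec.homography_true, spec.frame_size) < 1.0

    def test_transform_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            HomographyRegistrar().transform(np.zeros((64, 64)))

    def test_get_params_roundtrip(self):
        reg = HomographyRegistrar(ratio=0.6)
        assert reg.get_params()["ratio"] == 0.6
        reg.set_params(ratio=0.8)
        assert reg.ratio == 0.8


class TestBuildPairedDataset:
    def test_identity_dataset_registers_cleanly(self, tmp_path):
        generate_donor_dataset(
            tmp_path / "ds", n_donors=1, cells_per_donor=10, seed=11,
            homography=identity_homography(),
        )
        manifest = build_paired_dataset(tmp_path / "ds", tmp_path / "pairs", size=32, seed=0)
        assert (manifest["status"] == "failed").sum() == 0
        assert (manifest.loc[manifest["status"] == "ok", "rmse"] < 0.5).all()
        ok = manifest[manifest["status"] == "ok"]
        first = ok.iloc[0]
        pair_dir = tmp_path / "pairs" / first["donor"] / f"pair_{first['frame']}_{first['cell']}"
        assert (pair_dir / "bfi.tiff").exists()
        assert (pair_dir / "dsdna.tiff").exists()
        assert (pair_dir / "ssdna.tiff").exists()

    def test_blank_frame_fails_in_isolation(self, tmp_path):
        from virtustain.io import read_image, write_image

        generate_donor_dataset(
            tmp_path / "ds", n_donors=1, cells_per_donor=10, seed=11,
            homography=identity_homography(),
        )
        # blank out one frame's fluorescence; others must be unaffected
        victim = tmp_path / "ds" / "donor_1" / "dsdna" / "frame_0.tiff"
        write_image(victim, np.full_like(read_image(victim), 10))
        manifest = build_paired_dataset(tmp_path / "ds", tmp_path / "pairs", size=32, seed=0)
        by_frame = manifest.groupby("frame")["status"].agg(lambda s: set(s))
        assert by_frame[0] == {"failed"}
        assert all(st == {"ok"} for fr, st in by_frame.items() if fr != 0)

    def test_rerun_is_deterministic(self, tmp_path):
        generate_donor_dataset(tmp_path / "ds", n_donors=1, cells_per_donor=8, seed=5)
        m1 = build_paired_dataset(tmp_path / "ds", tmp_path / "p1", size=32, seed=2)
        m2 = build_paired_dataset(tmp_path / "ds", tmp_path / "p2", size=32, seed=2)
        pd.testing.assert_frame_equal(m1, m2)


class TestHomographyHelpers:
    def test_normalize_rejects_singular(self):
        with pytest.raises(ValueError):
            normalize_homography(np.zeros((3, 3)))

    def test_patchbox_validation(self):
        with pytest.raises(ValueError):
            PatchBox(0, 0, 0, 5)

    def test_match_distance_ordering_enforced(self):
        with pytest.raises(ValueError):
            KeypointMatch((0, 0), (0, 0), dist_best=0.9, dist_second=0.2)
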