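"""Histogram-mode background estimation: the mean of the three most frequent
intensities is the patch noise level, and the dsDNA background positions
transfer to the ssDNA channel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtustain.denoising import (
    denoise_pair,
    estimate_dsdna_noise,
    estimate_ssdna_noise,
    qc_histogram,
    subtract_noise,
    PairedBackgroundDenoiser,
)
from virtustain.synthetic import cell_box, random_scene, render_scene


def _mode_patch():
    """256x256 patch: 30k px of 5, 20k px of 6, 10k px of 4, rest 200."""
    flat = np.full(256 * 256, 200, dtype=np.uint8)
    flat[:30_000] = 5
    flat[30_000:50_000] = 6
    flat[50_000:60_000] = 4
    return flat.reshape(256, 256)


class TestEstimate:
    def test_top_three_mode_mean(self):
        est = estimate_dsdna_noise(_mode_patch())
        assert set(est.top_values) == {4, 5, 6}
        assert est.noise_value == pytest.approx(5.0)
        # every saved position holds one of the top values
        patch = _mode_patch()
        vals = patch[est.bg_positions[:, 0], est.bg_positions[:, 1]]
        assert set(np.unique(vals)) == {4, 5, 6}
        assert len(est.bg_positions) == 60_000

    def test_constant_patch_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            est = estimate_dsdna_noise(np.full((8, 8), 7, dtype=np.uint8))
        assert est.noise_value == pytest.approx(7.0)

    def test_synthetic_background_mode_recovered(self):
        spec = random_scene(2, bg_jitter=1, homography="identity")
        render = render_scene(spec)
        r0, c0, r1, c1 = cell_box(spec.cells[0])
        est = estimate_dsdna_noise(render.dsdna[r0:r1, c0:c1])
        assert set(est.top_values) == {spec.bg_level_ds - 1, spec.bg_level_ds,
                                       spec.bg_level_ds + 1}
        assert est.noise_value == pytest.approx(spec.bg_level_ds)

    def test_tie_break_prefers_lower_intensity(self):
        patch = np.array([[1, 1, 2, 2], [3, 3, 4, 4], [5, 5, 6, 6], [9, 9, 9, 9]],
                         dtype=np.uint8)
        est = estimate_dsdna_noise(patch)
        assert est.top_values == (9, 1, 2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 30, (16, 16)).astype(np.uint8)
        est = estimate_dsdna_noise(patch)
        shuffled = rng.permutation(patch.ravel()).reshape(patch.shape)
        assert estimate_dsdna_noise(shuffled).noise_value == est.noise_value


class TestSubtract:
    def test_subtracts_and_clips(self):
        out = subtract_noise(np.array([[10, 200]], dtype=np.uint8), 10)
        np.testing.assert_array_equal(out, [[0, 190]])

    def test_zero_noise_is_identity(self, rng):
        patch = rng.integers(0, 255, (12, 12)).astype(np.uint8)
        np.testing.assert_array_equal(subtract_noise(patch, 0), patch)

    def test_clips_below_zero(self):
        np.testing.assert_array_equal(subtract_noise(np.array([[3]], dtype=np.uint8), 10), [[0]])

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            subtract_noise(np.zeros((2, 2), dtype=np.uint8), -1)

    def test_fractional_noise_rounds_half_up(self):
        # noise 5.0 from {4,5,6}: 6 - 5.0 = 1.0; 4 - 5.0 clips to 0
        out = subtract_noise(np.array([[4, 5, 6, 10]], dtype=np.uint8), 4.5)
        np.testing.assert_array_equal(out, [[0, 1, 2, 6]])


class TestSsDnaTransfer:
    def test_constant_ss_patch(self):
        est = estimate_dsdna_noise(_mode_patch())
        ss = np.full((256, 256), 12, dtype=np.uint8)
        assert estimate_ssdna_noise(ss, est) == pytest.approx(12.0)

    def test_positional_mean(self):
        est = estimate_dsdna_noise(_mode_patch())
        ss = np.full((256, 256), 250, dtype=np.uint8)
        ss[est.bg_positions[:, 0], est.bg_positions[:, 1]] = 8
        assert estimate_ssdna_noise(ss, est) == pytest.approx(8.0)

    def test_equals_ds_estimate_on_identical_patch(self, rng):
        patch = rng.integers(0, 40, (32, 32)).astype(np.uint8)
        est = estimate_dsdna_noise(patch)
        ss_noise = estimate_ssdna_noise(patch, est)
        assert ss_noise == pytest.approx(np.mean(
            patch[np.isin(patch, est.top_values)]
        ))

    def test_shape_mismatch_rejected(self):
        est = estimate_dsdna_noise(_mode_patch())
        with pytest.raises(ValueError):
            estimate_ssdna_noise(np.zeros((4, 4), dtype=np.uint8), est)


class TestDenoisePair:
    def test_jitter_free_scene_background_becomes_zero(self):
        spec = random_scene(4, bg_jitter=0, homography="identity")
        render = render_scene(spec)
        for cell in spec.cells:
            r0, c0, r1, c1 = cell_box(cell)
            ds = render.dsdna[r0:r1, c0:c1]
            ss = render.ssdna[r0:r1, c0:c1]
            ds_c, ss_c, nd, ns = denoise_pair(ds, ss)
            assert nd == spec.bg_level_ds and ns == spec.bg_level_ss
            bg = render.labels[r0:r1, c0:c1] < 0
            assert np.all(ds_c[bg] == 0) and np.all(ss_c[bg] == 0)
            # in-cell pixels lose exactly the background offset
            cell_mask = ~bg
            np.testing.assert_array_equal(
                ds_c[cell_mask], ds[cell_mask] - spec.bg_level_ds
            )

    def test_already_clean_pair_unchanged_where_nonzero(self):
        spec = random_scene(6, bg_jitter=0, homography="identity")
        render = render_scene(spec)
        r0, c0, r1, c1 = cell_box(spec.cells[0])
        ds = render.dsdna[r0:r1, c0:c1]
        ss = render.ssdna[r0:r1, c0:c1]
        ds1, ss1, *_ = denoise_pair(ds, ss)
        ds2, ss2, nd, ns = denoise_pair(ds1, ss1)
        assert nd == 0.0 and ns == 0.0
        np.testing.assert_array_equal(ds1, ds2)
        np.testing.assert_array_equal(ss1, ss2)

    def test_deterministic_for_same_seed(self):
        a = render_scene(random_scene(9))
        b = render_scene(random_scene(9))
        ra = denoise_pair(a.dsdna, a.ssdna)
        rb = denoise_pair(b.dsdna, b.ssdna)
        np.testing.assert_array_equal(ra[0], rb[0])
        assert ra[2] == rb[2] and ra[3] == rb[3]

    def test_transformer_interface(self):
        spec = random_scene(4, bg_jitter=0, homography="identity")
        render = render_scene(spec)
        r0, c0, r1, c1 = cell_box(spec.cells[0])
        X = np.stack([np.stack([render.dsdna[r0:r1, c0:c1],
                                render.ssdna[r0:r1, c0:c1]])])
        den = PairedBackgroundDenoiser().fit(X)
        out = den.transform(X)
        assert out.shape == X.shape
        assert den.noise_log_[0]["ds_noise"] == spec.bg_level_ds


class TestQcHistogram:
    def test_all_zero_patch_gives_empty_histogram(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert qc_histogram(z, z).empty

    def test_direct_count_excluding_zeros(self):
        patch = np.array([[0, 5, 5]], dtype=np.uint8)
        df = qc_histogram(patch, patch)
        assert df.to_dict("records") == [
            {"intensity": 5, "count_before": 2, "count_after": 2}
        ]

    def test_background_line_disappears_after_denoising(self):
        spec = random_scene(4, bg_jitter=0, homography="identity")
        render = render_scene(spec)
        r0, c0, r1, c1 = cell_box(spec.cells[0])
        ds = render.dsdna[r0:r1, c0:c1]
        ds_c, *_ = denoise_pair(ds, render.ssdna[r0:r1, c0:c1])
        df = qc_histogram(ds, ds_c).set_index("intensity")
        lv = spec.bg_level_ds
        # the dominant background bin is the histogram's outstanding line
        assert df.loc[lv, "count_before"] == df["count_before"].max()
        assert lv not in df[df["count_after"] > 0].index or df.loc[lv, "count_after"] < 0.05 * df.loc[lv, "count_before"]
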