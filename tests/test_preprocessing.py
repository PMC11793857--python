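"""Normalization, cropping, patching, GH crops and sagittal flips."""

import numpy as np
import pytest

from xcelunet.core import CTVolume, LabelVolume
from xcelunet.preprocessing import (
    PatchSet,
    crop_to_labels,
    extract_gh_crop,
    extract_patches,
    hu_normalize,
    sagittal_flip,
    stitch_patches,
)
from xcelunet.synthetic import PhantomParams, generate_phantom


def _ct(data, units="HU"):
    return CTVolume(np.asarray(data, dtype=np.float32), (1.0,) * 3, units)


class TestHuNormalize:
    @pytest.mark.parametrize("hu,expected", [
        (-1024.0, 0.0),                    # lower clip bound (air)
        (2500.0, 1.0),                     # upper clip bound (cortical bone)
        (0.0, 1024.0 / 3524.0),            # water
        (-2000.0, 0.0),                    # clipped below
        (4000.0, 1.0),                     # clipped above
    ])
    def test_values(self, hu, expected):
        vol = _ct(np.full((4, 4, 4), hu))
        out = hu_normalize(vol)
        assert out.units == "normalized"
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_monotone_and_bounded(self, rng):
        x = rng.uniform(-2000, 4000, size=(6, 6, 6))
        out = hu_normalize(_ct(np.sort(x, axis=None).reshape(6, 6, 6))).data
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert (np.diff(out.ravel()) >= 0).all()

    def test_idempotent_on_normalized(self, rng):
        out = hu_normalize(_ct(rng.uniform(-500, 2000, (4, 4, 4))))
        again = hu_normalize(out)
        np.testing.assert_array_equal(out.data, again.data)

    def test_nonfinite_rejected(self):
        bad = np.zeros((3, 3, 3))
        bad[1, 1, 1] = np.nan
        with pytest.raises(ValueError):
            hu_normalize(_ct(bad))


class TestCropToLabels:
    def test_tight_box(self):
        lab = np.zeros((32, 32, 32), dtype=np.int16)
        lab[10:21, 10:21, 10:21] = 1
        vol, labc, offset = crop_to_labels(_ct(np.ones((32,) * 3)),
                                           LabelVolume(lab, (1.0,) * 3))
        assert labc.data.shape == (11, 11, 11)
        assert offset == (10, 10, 10)

    def test_full_grid_identity(self):
        lab = np.ones((8, 8, 8), dtype=np.int16)
        _, labc, offset = crop_to_labels(_ct(np.zeros((8,) * 3)),
                                         LabelVolume(lab, (1.0,) * 3))
        assert labc.data.shape == (8, 8, 8) and offset == (0, 0, 0)

    def test_matches_exhaustive_scan(self, rng):
        lab = (rng.random((20, 20, 20)) < 0.01).astype(np.int16)
        lab[7, 3, 15] = 1  # guarantee nonempty
        _, labc, offset = crop_to_labels(_ct(np.zeros((20,) * 3)),
                                         LabelVolume(lab, (1.0,) * 3))
        # brute-force voxel scan oracle
        lo = [20, 20, 20]
        hi = [0, 0, 0]
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    if lab[i, j, k]:
                        for ax, v in enumerate((i, j, k)):
                            lo[ax] = min(lo[ax], v)
                            hi[ax] = max(hi[ax], v)
        assert offset == tuple(lo)
        assert labc.data.shape == tuple(h - l + 1 for l, h in zip(lo, hi))

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            crop_to_labels(_ct(np.zeros((4,) * 3)),
                           LabelVolume(np.zeros((4,) * 3, np.int16), (1.0,) * 3))

    def test_inverse_offset_restores_coordinates(self, rng):
        lab = np.zeros((24, 24, 24), dtype=np.int16)
        pts = rng.integers(5, 18, size=(10, 3))
        lab[tuple(pts.T)] = 1
        _, labc, offset = crop_to_labels(_ct(np.zeros((24,) * 3)),
                                         LabelVolume(lab, (1.0,) * 3))
        restored = np.argwhere(labc.data) + np.array(offset)
        assert {tuple(p) for p in restored} == {tuple(p) for p in pts}


class TestExtractPatches:
    def test_axis_280_gives_two_windows_quarter_overlap(self):
        ps = extract_patches(np.zeros((280, 160, 160), np.float32),
                             patch_edge=160)
        offsets0 = sorted({o[0] for _, o in ps.patches})
        assert offsets0 == [0, 120]         # overlap 40 voxels = 25% of 160
        assert len(ps.patches) == 2

    def test_exact_fit_single_window(self):
        ps = extract_patches(np.zeros((160,) * 3, np.float32), patch_edge=160)
        assert len(ps.patches) == 1 and ps.patches[0][1] == (0, 0, 0)

    def test_full_coverage_axis_400(self):
        ps = extract_patches(np.zeros((400, 160, 160), np.float32),
                             patch_edge=160)
        offsets0 = sorted({o[0] for _, o in ps.patches})
        assert len(offsets0) == 3
        covered = np.zeros(400, dtype=bool)  # voxelwise union oracle
        for o in offsets0:
            covered[o:o + 160] = True
        assert covered.all()
        for a, b in zip(offsets0, offsets0[1:]):
            assert a + 160 - b >= 0.25 * 160

    def test_small_volume_padded(self):
        ps = extract_patches(np.ones((40, 40, 40), np.float32), patch_edge=48)
        assert ps.patches[0][0].shape == (48, 48, 48)
        assert ps.pad == (4, 4, 4)

    def test_bad_edge_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((8,) * 3, np.float32), patch_edge=0)


class TestStitchPatches:
    def test_single_patch_identity(self, rng):
        probs = rng.random((3, 16, 16, 16)).astype(np.float32)
        probs /= probs.sum(axis=0)
        ps = PatchSet([(probs, (0, 0, 0))], 16, (16, 16, 16))
        np.testing.assert_allclose(stitch_patches(ps), probs, rtol=1e-6)

    def test_equal_values_unchanged_in_overlap(self, rng):
        probs = rng.random((3, 16, 16, 16)).astype(np.float32)
        probs /= probs.sum(axis=0)
        full = np.tile(probs[:, :1], (1, 24, 1, 1))[:, :24]
        a, b = full[:, :16], full[:, 8:]
        ps = PatchSet([(a, (0, 0, 0)), (b, (8, 0, 0))], 16, (24, 16, 16))
        out = stitch_patches(ps)
        np.testing.assert_allclose(out, full, rtol=1e-5)

    def test_overlap_mean(self):
        a = np.full((1, 4, 4, 4), 0.2)
        b = np.full((1, 4, 4, 4), 0.6)
        ps = PatchSet([(a, (0, 0, 0)), (b, (0, 0, 0))], 4, (4, 4, 4))
        out = stitch_patches(ps, renormalize=False)
        np.testing.assert_allclose(out, 0.4)

    def test_uncovered_voxel_rejected(self):
        a = np.full((1, 4, 4, 4), 0.5)
        ps = PatchSet([(a, (0, 0, 0))], 4, (8, 4, 4))
        with pytest.raises(ValueError):
            stitch_patches(ps)


class TestGHCrop:
    def test_crop_centred_on_joint(self, clean_phantom):
        vol = hu_normalize(clean_phantom.ct)
        crop = extract_gh_crop(vol, clean_phantom.labels, crop_edge=32)
        # analytic geometry: head centre and glenoid point are known
        p = clean_phantom.params
        extent = np.array(p.grid_shape) * p.spacing_mm
        c0 = np.array([0.58 * extent[0], 0.5 * extent[1],
                       0.5 * extent[2] - 0.10 * extent[2]])
        glenoid = c0 + np.array([0.0, 0.0, p.head_radius_mm + p.joint_gap_mm])
        true_mid = (c0 + glenoid) / 2.0
        assert np.abs(np.array(crop.center_voxel) - true_mid).max() <= 2.0
        assert crop.data.shape == (32, 32, 32)

    def test_missing_scapula_rejected(self, clean_phantom):
        lab = clean_phantom.labels.data.copy()
        lab[lab == 2] = 0
        with pytest.raises(ValueError):
            extract_gh_crop(hu_normalize(clean_phantom.ct),
                            LabelVolume(lab, (1.0,) * 3), crop_edge=32)

    def test_border_crop_zero_padded(self, clean_phantom):
        vol = hu_normalize(clean_phantom.ct)
        crop = extract_gh_crop(vol, clean_phantom.labels, crop_edge=64)
        assert crop.data.shape == (64, 64, 64)  # padded despite 48^3 source


class TestSagittalFlip:
    def test_involution(self, clean_phantom):
        vol = hu_normalize(clean_phantom.ct)
        crop = extract_gh_crop(vol, clean_phantom.labels, crop_edge=32,
                               truth=clean_phantom.truth)
        twice = sagittal_flip(sagittal_flip(crop))
        np.testing.assert_array_equal(twice.data, crop.data)
        assert twice.labels == crop.labels

    def test_mirrored_phantom_oracle(self):
        # flipping a noiseless right-shoulder volume matches the
        # independently generated left-shoulder phantom voxelwise
        kw = dict(grid_shape=(48, 48, 48), spacing_mm=1.0,
                  head_radius_mm=10.0, joint_gap_mm=3.0, noise_sd_hu=0.0,
                  seed=2)
        right = generate_phantom(PhantomParams(side="right", **kw))
        left = generate_phantom(PhantomParams(side="left", **kw))
        np.testing.assert_array_equal(right.ct.data[:, :, ::-1], left.ct.data)
        np.testing.assert_array_equal(right.labels.data[:, :, ::-1],
                                      left.labels.data)
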