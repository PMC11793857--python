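"""GradCAM: gradient correctness on an analytic toy model, map properties,
overlay rendering and localization scoring."""

import numpy as np
import pytest

from xcelunet.autodiff import Tensor
from xcelunet.core import GHCrop
from xcelunet.gradcam import compute_gradcam, localization_score, overlay
from xcelunet.layers import Dense
from xcelunet.network import NetworkConfig, build_model


class _ToyModel:
    """Analytic stand-in: 2 bottleneck feature maps on a 2^3 grid and a
    purely linear classification path, so y^{s,c} = sum_f W[f,c] * mean(A_f)
    and the expected activation map is ReLU(sum_f W[f,c]/Z * A_f)."""

    def __init__(self, feature_maps: np.ndarray, head_weights: np.ndarray):
        rng = np.random.default_rng(0)
        self.A = feature_maps.astype(np.float32)      # (2, 2, 2, 2)
        f = feature_maps.shape[0]
        self.cls_dense1 = Dense(f, f, rng)
        self.cls_dense1.w.data = np.eye(f, dtype=np.float32)
        self.cls_dense1.b.data[:] = 0.0
        self.cls_dense2 = Dense(f, f, rng)
        self.cls_dense2.w.data = np.eye(f, dtype=np.float32)
        self.cls_dense2.b.data[:] = 0.0
        self.os_head = Dense(f, 3, rng)
        self.os_head.w.data = head_weights.astype(np.float32)
        self.os_head.b.data[:] = 0.0
        self.js_head = self.os_head
        self.hsa_head = Dense(f, 1, rng)

    def _encode(self, x):
        return Tensor(self.A[None]), []

    def score(self, a: np.ndarray, c: int) -> float:
        """Closed-form y for finite-difference checks (positive maps keep
        the ReLUs in the dense path transparent)."""
        pooled = a.reshape(a.shape[0], -1).mean(axis=1)
        return float(pooled @ self.os_head.w.data[:, c])


@pytest.fixture()
def toy(rng):
    a = rng.uniform(0.5, 2.0, size=(2, 2, 2, 2))
    w = rng.normal(size=(2, 3))  # Dense layout (features, classes)
    return _ToyModel(a, w)


def test_gradients_match_finite_differences(toy):
    act = compute_gradcam(toy, np.zeros((8, 8, 8), np.float32), "OS", 1)
    z = act.z
    assert z == 8
    for f in range(2):
        eps = 1e-3
        ap = toy.A.copy()
        am = toy.A.copy()
        ap[f, 0, 0, 0] += eps
        am[f, 0, 0, 0] -= eps
        fd = (toy.score(ap, 1) - toy.score(am, 1)) / (2 * eps)
        # alpha_f is the spatial mean of a constant gradient field, so the
        # per-voxel gradient equals alpha_f * Z / Z = alpha_f... compare
        # alpha_f against the finite-difference derivative directly
        assert abs(act.alpha[f] - fd) / (abs(fd) + 1e-9) < 1e-3


def test_map_equals_hand_computed_weighted_sum(toy):
    act = compute_gradcam(toy, np.zeros((8, 8, 8), np.float32), "OS", 2)
    w = toy.os_head.w.data[:, 2]       # linear path: dy/dA_f,ijk = w_f / Z
    expected = np.maximum((w[:, None, None, None] / act.z * toy.A).sum(0), 0)
    np.testing.assert_allclose(act.raw, expected, rtol=1e-4, atol=1e-7)


def test_nonnegativity_over_random_weights(rng):
    a = rng.uniform(0.2, 1.5, size=(2, 2, 2, 2))
    for _ in range(100):
        toy = _ToyModel(a, rng.normal(size=(2, 3)))
        act = compute_gradcam(toy, np.zeros((8, 8, 8), np.float32), "OS",
                              int(rng.integers(0, 3)))
        assert act.raw.min() >= 0.0
        assert act.heatmap.min() >= 0.0


def test_homogeneity_in_head_weights(toy):
    act1 = compute_gradcam(toy, np.zeros((8, 8, 8), np.float32), "OS", 0)
    toy.os_head.w.data *= 3.0
    act3 = compute_gradcam(toy, np.zeros((8, 8, 8), np.float32), "OS", 0)
    np.testing.assert_allclose(act3.raw, 3.0 * act1.raw, rtol=1e-4, atol=1e-7)


def test_zeroed_head_gives_zero_map(rng):
    model = build_model(NetworkConfig(seed=0))
    for p in (model.os_head.w, model.os_head.b, model.cls_dense1.w,
              model.cls_dense1.b, model.cls_dense2.w, model.cls_dense2.b):
        p.data[:] = 0.0
    crop = rng.random((16, 16, 16), dtype=np.float32)
    act = compute_gradcam(model, crop, "OS", 0)
    assert (act.heatmap == 0).all()


def test_bottleneck_z_is_1000_for_80_cube():
    model = build_model(NetworkConfig(seed=0))
    act = compute_gradcam(model, np.zeros((80, 80, 80), np.float32), "HSA", 0)
    assert act.z == 1000
    assert act.raw.shape == (10, 10, 10)
    assert act.heatmap.shape == (80, 80, 80)


def test_out_of_range_class_rejected():
    model = build_model(NetworkConfig(seed=0))
    with pytest.raises(ValueError):
        compute_gradcam(model, np.zeros((16, 16, 16), np.float32), "HSA", 1)
    with pytest.raises(ValueError):
        compute_gradcam(model, np.zeros((16, 16, 16), np.float32), "XX", 0)


class TestOverlay:
    def _act(self, heat):
        from xcelunet.gradcam import ActivationMap

        return ActivationMap(heatmap=heat, raw=heat, class_set="OS",
                             class_index=0, alpha=np.zeros(2), z=heat.size)

    def test_zero_map_pure_grayscale(self, rng):
        crop = rng.random((8, 8, 8), dtype=np.float32)
        img = overlay(self._act(np.zeros((8, 8, 8), np.float32)), crop)
        # grayscale: all three RGB channels equal
        np.testing.assert_allclose(img[..., 0], img[..., 1], atol=1e-6)
        np.testing.assert_allclose(img[..., 1], img[..., 2], atol=1e-6)

    def test_constant_map_uniform_tint(self):
        crop = np.zeros((8, 8, 8), np.float32)
        img = overlay(self._act(np.ones((8, 8, 8), np.float32)), crop)
        flat = img.reshape(-1, 3)
        assert np.allclose(flat, flat[0], atol=1e-6)

    def test_peak_heat_at_map_argmax(self, rng):
        crop = np.zeros((8, 8, 8), np.float32)
        heat = np.zeros((8, 8, 8), np.float32)
        heat[4, 2, 6] = 1.0
        img = overlay(self._act(heat), crop, cmap="hot")
        axial = img[:, 0:8]  # axis-0 mid-slice is index 4 -> shows the peak
        peak = np.unravel_index(axial.sum(axis=-1).argmax(), (8, 8))
        assert peak == (2, 6)


class TestLocalization:
    def _act(self, heat):
        from xcelunet.gradcam import ActivationMap

        return ActivationMap(heatmap=heat.astype(np.float32), raw=heat,
                             class_set="OS", class_index=0,
                             alpha=np.zeros(2), z=heat.size)

    def test_all_mass_inside_region(self):
        heat = np.zeros((10, 10, 10))
        heat[3:5, 3:5, 3:5] = 1.0
        region = heat > 0
        assert localization_score(self._act(heat), region).fraction == 1.0

    def test_all_mass_outside_region(self):
        heat = np.zeros((10, 10, 10))
        heat[0, 0, 0] = 1.0
        region = np.zeros((10, 10, 10), bool)
        region[7:, 7:, 7:] = True
        assert localization_score(self._act(heat), region).fraction == 0.0

    def test_uniform_map_gives_region_fraction(self):
        heat = np.ones((10, 10, 10))
        region = np.zeros((10, 10, 10), bool)
        region[:2] = True
        score = localization_score(self._act(heat), region)
        assert score.fraction == pytest.approx(0.2)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            localization_score(self._act(np.ones((4, 4, 4))),
                               np.zeros((4, 4, 4), bool))
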