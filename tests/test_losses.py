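"""Region/contour losses, schedules, distance weights and class balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xcelunet.autodiff import Tensor
from xcelunet.losses import (
    alpha_schedule,
    beta_fraction,
    class_weights,
    classification_loss,
    contour_loss,
    dice_score,
    distance_weight_maps,
    edge_targets,
    one_hot,
    region_loss,
)


def _onehot_pred(labels, n=3):
    return one_hot(labels, n)


class TestDice:
    def test_perfect_prediction(self):
        lab = np.zeros((1, 4, 4, 4), dtype=int)
        lab[0, 1:3] = 1
        t = _onehot_pred(lab)
        assert dice_score(t, t) == pytest.approx(1.0, abs=1e-5)

    def test_disjoint_foregrounds(self):
        a = np.zeros((1, 4, 4, 4), dtype=int)
        b = np.zeros((1, 4, 4, 4), dtype=int)
        a[0, 0] = 1
        a[0, 1] = 2
        b[0, 3] = 1
        b[0, 2] = 2
        assert dice_score(_onehot_pred(a), _onehot_pred(b)) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_half_coverage_gives_two_thirds(self):
        # |pred| = |target|/2, no false positives: 2*(n/2)/(n/2 + n) = 2/3
        target = np.zeros((1, 4, 4, 4), dtype=int)
        target[0, :2] = 1
        pred = np.zeros((1, 4, 4, 4), dtype=int)
        pred[0, :1] = 1
        t = _onehot_pred(target)
        p = _onehot_pred(pred)
        # restrict to the foreground class only (class 2 empty in both)
        d_fg = 2 * (p[:, 1] * t[:, 1]).sum() / (p[:, 1].sum() + t[:, 1].sum())
        assert d_fg == pytest.approx(2 / 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((1, 3, 4, 4, 4)), np.zeros((1, 3, 4, 4, 2)))


class TestAlphaSchedule:
    @pytest.mark.parametrize("t,expected", [(0, 1.0), (50, 0.75), (100, 0.5),
                                            (150, 0.5), (1000, 0.5)])
    def test_values(self, t, expected):
        assert alpha_schedule(t) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            alpha_schedule(-1)

    def test_non_increasing_and_clamped(self):
        vals = [alpha_schedule(t) for t in range(0, 300)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert min(vals) == 0.5


class TestDistanceWeights:
    def test_boundary_voxel_weight(self):
        lab = np.zeros((8, 8, 8), dtype=int)
        lab[:4] = 1
        w_near, w_far = distance_weight_maps(lab, 1.0, gamma=5.0, tau_mm=3.0)
        # on the inter-class boundary d=0: w_near = 1 + gamma
        assert w_near.max() == pytest.approx(6.0)
        assert w_far.min() == pytest.approx(1.0)

    def test_far_field_limits(self):
        lab = np.zeros((40, 8, 8), dtype=int)
        lab[:2] = 1
        w_near, w_far = distance_weight_maps(lab, 1.0, gamma=5.0, tau_mm=3.0)
        assert w_near[-1].max() < 1.001          # w_near -> 1 for d >> tau
        assert w_far[-1].min() > 5.99            # w_far -> 1 + gamma

    def test_distances_match_bruteforce(self, rng):
        lab = (rng.random((10, 10, 10)) < 0.2).astype(int)
        lab[5, 5, 5] = 1
        lab[0, 0, 0] = 0
        w_near, _ = distance_weight_maps(lab, 1.0, gamma=5.0, tau_mm=3.0)
        # invert w_near to recover d and compare to exhaustive search
        from scipy import ndimage

        hi = ndimage.maximum_filter(lab, size=3)
        lo = ndimage.minimum_filter(lab, size=3)
        boundary = np.argwhere(hi != lo)
        for p in [(0, 0, 0), (9, 9, 9), (5, 0, 5), (2, 7, 4)]:
            d_brute = np.sqrt(((boundary - p) ** 2).sum(axis=1)).min()
            d_impl = -3.0 * np.log((w_near[p] - 1.0) / 5.0)
            assert d_impl == pytest.approx(d_brute, abs=1e-3)

    def test_single_class_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            w_near, w_far = distance_weight_maps(np.zeros((4, 4, 4), int), 1.0)
        assert (w_near == 1).all() and (w_far == 1).all()


class TestEdgeTargets:
    def test_uniform_volume_no_edges(self):
        assert (edge_targets(np.ones((5, 5, 5), int)) == 0).all()

    def test_single_voxel_is_edge(self):
        lab = np.zeros((5, 5, 5), int)
        lab[2, 2, 2] = 1
        assert edge_targets(lab)[2, 2, 2] == 1

    def test_sphere_edges_match_neighbourhood_scan(self):
        z, y, x = np.indices((16, 16, 16))
        lab = ((z - 8) ** 2 + (y - 8) ** 2 + (x - 8) ** 2 <= 25).astype(int)
        edges = edge_targets(lab)
        # brute-force scan: a voxel is an edge voxel of class 1 iff its
        # 3x3x3 neighbourhood is not constant-equal to its own mask value
        count = 0
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    lo = (max(i - 1, 0), max(j - 1, 0), max(k - 1, 0))
                    hi = (min(i + 2, 16), min(j + 2, 16), min(k + 2, 16))
                    nb = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                    if nb.min() != nb.max():
                        count += 1
        assert int((edges == 1).sum()) == count

    def test_lower_class_wins_overlap(self):
        lab = np.zeros((6, 6, 6), int)
        lab[:3] = 1
        lab[3:] = 2
        edges = edge_targets(lab)
        interface = edges[2:4]
        assert (interface[interface > 0] == 1).all()


class TestSegLosses:
    def test_perfect_prediction_zero_loss(self):
        lab = np.zeros((1, 8, 8, 8), dtype=int)
        lab[0, 2:5] = 1
        t = one_hot(lab, 3)
        pred = Tensor(t)
        l_r = region_loss(pred, t, alpha=0.7)
        edges = np.stack([edge_targets(l) for l in lab])
        te = one_hot(edges, 3)
        l_c = contour_loss(Tensor(te), te, beta=beta_fraction(edges))
        assert float(l_r.data) == pytest.approx(0.0, abs=1e-4)
        assert float(l_c.data) == pytest.approx(0.0, abs=1e-4)

    def test_alpha_one_reduces_to_dice_loss(self, rng):
        lab = (rng.random((1, 6, 6, 6)) < 0.3).astype(int)
        t = one_hot(lab, 3)
        pred = rng.dirichlet(np.ones(3), size=(1, 6, 6, 6)).transpose(
            0, 4, 1, 2, 3
        ).astype(np.float32)
        l_r = region_loss(Tensor(pred), t, alpha=1.0)
        d = dice_score(pred, t)
        assert float(l_r.data) == pytest.approx(1.0 - d, abs=1e-5)

    def test_plug_in_arithmetic(self):
        # L_r = 1 - (0.5*0.8 + 0.5*0.6) = 0.3 by direct substitution
        assert 1.0 - (0.5 * 0.8 + 0.5 * 0.6) == pytest.approx(0.3)

    def test_loss_decreases_toward_target(self):
        lab = np.zeros((1, 4, 4, 4), dtype=int)
        lab[0, 1:3] = 1
        t = one_hot(lab, 3)
        losses = []
        for conf in (0.4, 0.6, 0.8, 0.95):
            pred = np.full((1, 3, 4, 4, 4), (1 - conf) / 2, dtype=np.float32)
            pred[0, 0][lab[0] == 0] = conf
            pred[0, 1][lab[0] == 1] = conf
            pred[0, 2] = (1 - pred[0, 0] - pred[0, 1]).clip(1e-6, 1)
            losses.append(float(region_loss(Tensor(pred), t, 0.5).data))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_non_probability_rejected(self):
        t = one_hot(np.zeros((1, 2, 2, 2), int), 3)
        with pytest.raises(ValueError):
            region_loss(Tensor(t * 3.0 - 1.0), t, 0.5)


class TestClassWeights:
    def test_two_equal_classes(self):
        assert class_weights([10, 10]).weights == (0.5, 0.5)

    def test_three_equal_classes(self):
        np.testing.assert_allclose(class_weights([7, 7, 7]).weights, 1 / 3)

    def test_hsa_frequencies(self):
        k = class_weights([56.1, 43.9]).weights
        assert round(k[0], 3) == 0.439 and round(k[1], 3) == 0.561

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights([5, 0, 3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=2,
                    max_size=6))
    def test_weights_normalize(self, counts):
        assert sum(class_weights(counts).weights) == pytest.approx(1.0)


class TestClassificationLoss:
    def _weights(self):
        return {"os": class_weights([1, 1, 1]), "js": class_weights([1, 1, 1]),
                "hsa": class_weights([1, 1])}

    def test_perfect_prediction_zero(self):
        truth = {"os": np.array([1]), "js": np.array([2]),
                 "hsa": np.array([1])}
        heads = {
            "os": Tensor(np.array([[0.0, 1.0, 0.0]], np.float32)),
            "js": Tensor(np.array([[0.0, 0.0, 1.0]], np.float32)),
            "hsa": Tensor(np.array([[1.0]], np.float32)),
        }
        loss = classification_loss(heads, truth, self._weights())
        assert float(loss.data) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_closed_form(self):
        # uniform 3-way prediction with equal weights: K * ln 3 per task
        truth = {"os": np.array([0, 1]), "js": np.array([2, 0]),
                 "hsa": np.array([0, 1])}
        heads = {
            "os": Tensor(np.full((2, 3), 1 / 3, np.float32)),
            "js": Tensor(np.full((2, 3), 1 / 3, np.float32)),
            "hsa": Tensor(np.full((2, 1), 0.5, np.float32)),
        }
        loss = classification_loss(heads, truth, self._weights())
        expected = 2 * (np.log(3.0) / 3) + np.log(2.0) / 2
        assert float(loss.data) == pytest.approx(expected, rel=1e-4)

    def test_count_scale_invariance(self):
        w1 = {"os": class_weights([10, 20, 30]),
              "js": class_weights([5, 5, 5]), "hsa": class_weights([4, 6])}
        w2 = {"os": class_weights([20, 40, 60]),
              "js": class_weights([10, 10, 10]), "hsa": class_weights([8, 12])}
        truth = {"os": np.array([2]), "js": np.array([0]),
                 "hsa": np.array([0])}
        heads = {
            "os": Tensor(np.array([[0.2, 0.3, 0.5]], np.float32)),
            "js": Tensor(np.array([[0.6, 0.2, 0.2]], np.float32)),
            "hsa": Tensor(np.array([[0.3]], np.float32)),
        }
        l1 = classification_loss(heads, truth, w1)
        l2 = classification_loss(heads, truth, w2)
        assert float(l1.data) == pytest.approx(float(l2.data), rel=1e-6)


def test_logits_loss_matches_probability_loss(rng):
    """The numerically stable logit formulation computes the same value as
    the probability-based loss, with finite gradients at extreme logits."""
    from xcelunet.losses import classification_loss_from_logits

    z = {k: rng.normal(size=(5, n)).astype(np.float32)
         for k, n in (("os", 3), ("js", 3), ("hsa", 1))}
    truth = {"os": rng.integers(0, 3, 5), "js": rng.integers(0, 3, 5),
             "hsa": rng.integers(0, 2, 5)}
    w = {"os": class_weights([3, 4, 5]), "js": class_weights([2, 2, 2]),
         "hsa": class_weights([6, 4])}

    def softmax(a):
        e = np.exp(a - a.max(1, keepdims=True))
        return e / e.sum(1, keepdims=True)

    l_prob = classification_loss(
        {"os": Tensor(softmax(z["os"])), "js": Tensor(softmax(z["js"])),
         "hsa": Tensor(1 / (1 + np.exp(-z["hsa"])))}, truth, w)
    l_logit = classification_loss_from_logits(
        {k: Tensor(v) for k, v in z.items()}, truth, w)
    assert float(l_logit.data) == pytest.approx(float(l_prob.data), rel=1e-5)

    extreme = Tensor(np.array([[80.0, -80.0, -80.0]], np.float32),
                     requires_grad=True)
    loss = classification_loss_from_logits(
        {"os": extreme, "js": Tensor(np.zeros((1, 3), np.float32)),
         "hsa": Tensor(np.zeros((1, 1), np.float32))},
        {"os": [1], "js": [0], "hsa": [0]},
        {"os": class_weights([1, 1, 1]), "js": class_weights([1, 1, 1]),
         "hsa": class_weights([1, 1])})
    loss.backward()
    assert np.isfinite(extreme.grad).all()
    assert np.abs(extreme.grad).max() <= 1.0  # bounded: softmax - onehot


def test_beta_is_edge_fraction(rng):
    lab = (rng.random((2, 8, 8, 8)) < 0.3).astype(int)
    edges = np.stack([edge_targets(l) for l in lab])
    beta = beta_fraction(edges)
    assert beta == pytest.approx((edges != 0).sum() / edges.size)
    assert 0.0 <= beta <= 1.0
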