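"""Grad-CAM: neuron importance, map assembly, gradient capture, rendering."""

import numpy as np
import pytest

from simexplain import (ActivationStack, GradStack, Heatmap, ImagePair,
                        LabeledImage, NeuronWeights, cam, capture,
                        explain_pair, neuron_importance, normalize_and_resize,
                        overlay)

RNG = np.random.default_rng(777)


def loop_neuron_importance(grads):
    """Independent brute-force double loop over spatial positions."""
    h, w, K = grads.shape
    alpha = np.zeros(K)
    for k in range(K):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += grads[i, j, k]
        alpha[k] = s / (h * w)
    return alpha


def loop_cam(alpha, acts):
    h, w, K = acts.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for k in range(K):
                s += alpha[k] * acts[i, j, k]
            out[i, j] = max(0.0, s)
    return out


def random_pair(model, seed=0, label=1):
    rng = np.random.default_rng(seed)
    size = model.spec.input_size
    mk = lambda i: LabeledImage(
        (rng.random((*size, 3)) * 255).astype(np.uint8), f"c{i}", f"img{i}")
    return ImagePair(a=mk(0), b=mk(1), label=label)


class TestNeuronImportance:
    def test_constant_gradients(self):
        g = GradStack(grads=np.full((4, 4, 3), 2.5), target_mode="factual")
        w = neuron_importance(g)
        assert np.allclose(w.alpha, 2.5)
        assert w.Z == 16

    def test_small_arithmetic_case(self):
        g = GradStack(grads=np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None],
                      target_mode="factual")
        assert neuron_importance(g).alpha[0] == pytest.approx(2.5)

    def test_matches_loop_oracle(self):
        for _ in range(10):
            grads = RNG.standard_normal((5, 7, 4))
            got = neuron_importance(GradStack(grads, "factual")).alpha
            assert np.allclose(got, loop_neuron_importance(grads), atol=1e-12)


class TestCam:
    def test_negative_combination_is_zeroed(self):
        acts = ActivationStack(np.abs(RNG.standard_normal((3, 3, 1))) + 0.1,
                               branch="a", layer="conv3")
        h = cam(NeuronWeights(alpha=np.array([-1.0]), Z=9), acts)
        assert np.all(h.values == 0)

    def test_linear_in_weights(self):
        a1 = np.abs(RNG.standard_normal((4, 4)))
        acts = ActivationStack(np.stack([a1, a1], axis=-1), "a", "conv3")
        h = cam(NeuronWeights(alpha=np.array([1.0, 1.0]), Z=16), acts)
        assert np.allclose(h.values, 2 * a1)

    def test_k_mismatch_rejected(self):
        acts = ActivationStack(np.zeros((2, 2, 3)), "a", "conv3")
        with pytest.raises(ValueError, match="mismatch"):
            cam(NeuronWeights(alpha=np.zeros(2), Z=4), acts)

    def test_matches_loop_oracle(self):
        for _ in range(10):
            acts = RNG.standard_normal((6, 5, 3))
            alpha = RNG.standard_normal(3)
            got = cam(NeuronWeights(alpha, Z=30),
                      ActivationStack(acts, "a", "conv3")).values
            assert np.allclose(got, loop_cam(alpha, acts), atol=1e-12)


class TestCapture:
    def test_counterfactual_negates_gradients(self, tiny_model):
        pair = random_pair(tiny_model, seed=1)
        (_, gf_a), (_, gf_b), d = capture(tiny_model, pair, "factual")
        (_, gc_a), (_, gc_b), _ = capture(tiny_model, pair, "counterfactual")
        assert np.allclose(gc_a.grads, -gf_a.grads)
        assert np.allclose(gc_b.grads, -gf_b.grads)
        assert 0 < d < 1

    def test_identical_pair_has_identical_branches(self, tiny_model):
        px = (np.random.default_rng(2).random((16, 16, 3)) * 255).astype(np.uint8)
        pair = ImagePair(a=LabeledImage(px, "c", "i1"),
                         b=LabeledImage(px.copy(), "c", "i2"), label=0)
        (aa, _), (ab, _), _ = capture(tiny_model, pair, "factual")
        assert np.array_equal(aa.maps, ab.maps)

    def test_unknown_layer_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="target layer"):
            capture(tiny_model, random_pair(tiny_model, seed=3), "factual",
                    target_layer="conv9")

    def test_gradients_match_finite_differences(self, tiny_model):
        """Captured activation gradients are true derivatives of d."""
        pair = random_pair(tiny_model, seed=4)
        (acts_a, grads_a), (acts_b, _), _ = capture(tiny_model, pair, "factual")
        A = acts_a.maps[None].copy()
        B = acts_b.maps[None].copy()
        h, w, K = acts_a.maps.shape
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(30):
            i, j, k = rng.integers(h), rng.integers(w), rng.integers(K)
            old = A[0, i, j, k]
            A[0, i, j, k] = old + 1e-3
            up = tiny_model.forward_from_target_acts(A, B)[0]
            A[0, i, j, k] = old - 1e-3
            down = tiny_model.forward_from_target_acts(A, B)[0]
            A[0, i, j, k] = old
            fd = (up - down) / 2e-3
            if abs(fd) > 1e-8:
                assert grads_a.grads[i, j, k] == pytest.approx(fd, rel=1e-2)
                checked += 1
        assert checked >= 10


class TestExplainPair:
    def test_counterfactual_is_relu_of_negated_combination(self, tiny_model):
        pair = random_pair(tiny_model, seed=5)
        (acts_a, grads_a), _, _ = capture(tiny_model, pair, "factual")
        fact_alpha = neuron_importance(grads_a)
        combo = np.tensordot(acts_a.maps, fact_alpha.alpha, axes=([2], [0]))
        (acts_c, grads_c), _, _ = capture(tiny_model, pair, "counterfactual")
        counter = cam(neuron_importance(grads_c), acts_c).values
        assert np.allclose(counter, np.maximum(-combo, 0.0), atol=1e-9)

    def test_disjoint_support(self, tiny_model):
        pair = random_pair(tiny_model, seed=6)
        (acts, grads), _, _ = capture(tiny_model, pair, "factual")
        fact = cam(neuron_importance(grads), acts).values
        (acts_c, grads_c), _, _ = capture(tiny_model, pair, "counterfactual")
        counter = cam(neuron_importance(grads_c), acts_c).values
        assert not np.any((fact > 0) & (counter > 0))

    def test_metadata_and_range(self, tiny_model):
        pair = random_pair(tiny_model, seed=7)
        ha, hb = explain_pair(tiny_model, pair, "factual")
        assert (ha.branch, hb.branch) == ("a", "b")
        assert ha.mode == "factual" and ha.normalized
        assert ha.values.shape == (16, 16)
        assert ha.values.min() >= 0 and ha.values.max() <= 1


class TestNormalizeAndResize:
    def test_constant_positive_becomes_ones(self):
        raw = Heatmap(np.full((4, 4), 0.7), "factual", "a")
        out = normalize_and_resize(raw, (4, 4))
        assert np.all(out.values == 1.0)

    def test_all_zero_stays_zero(self):
        raw = Heatmap(np.zeros((4, 4)), "factual", "a")
        out = normalize_and_resize(raw, (8, 8))
        assert np.all(out.values == 0.0)

    def test_min_max_arithmetic(self):
        raw = Heatmap(np.array([[0.0, 1.0], [2.0, 3.0]]), "factual", "a")
        out = normalize_and_resize(raw, (2, 2))
        assert np.allclose(out.values, [[0, 1 / 3], [2 / 3, 1]])

    def test_upsample_preserves_range(self):
        raw = Heatmap(np.abs(RNG.standard_normal((4, 4))), "factual", "a")
        out = normalize_and_resize(raw, (32, 32))
        assert out.values.shape == (32, 32)
        assert out.values.min() >= 0 and out.values.max() <= 1


class TestOverlay:
    def test_alpha_extremes(self):
        img = (RNG.random((8, 8, 3)) * 255).astype(np.uint8)
        h = Heatmap(RNG.random((8, 8)), "factual", "a", normalized=True)
        assert np.array_equal(overlay(h, img, alpha=0.0), img)
        from matplotlib import colormaps
        expected = np.clip(np.round(colormaps["jet"](h.values)[:, :, :3] * 255),
                           0, 255).astype(np.uint8)
        assert np.array_equal(overlay(h, img, alpha=1.0), expected)

    def test_zero_heatmap_blend(self):
        img = np.full((8, 8, 3), 100, dtype=np.uint8)
        h = Heatmap(np.zeros((8, 8)), "factual", "a", normalized=True)
        from matplotlib import colormaps
        at_zero = colormaps["jet"](np.zeros((8, 8)))[:, :, :3] * 255
        expected = np.clip(np.round(0.5 * 100 + 0.5 * at_zero), 0, 255).astype(np.uint8)
        assert np.array_equal(overlay(h, img, alpha=0.5), expected)

    def test_size_mismatch(self):
        h = Heatmap(np.zeros((4, 4)), "factual", "a", normalized=True)
        with pytest.raises(ValueError, match="match"):
            overlay(h, np.zeros((8, 8, 3), dtype=np.uint8))
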