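"""Residual backbones and Gumbel-Softmax routing."""

import numpy as np
import pytest

import spottune3d as st
from spottune3d.backbones import build_agent, build_main_backbone
from spottune3d.nn import Tensor, no_grad
from spottune3d.routing import (SpotTuneNetwork, gumbel_noise,
                                per_image_gumbel, sample_policy)


@pytest.fixture()
def net(tiny_backbone, tiny_agent):
    return SpotTuneNetwork(tiny_backbone, tiny_agent, tau=100.0)


def _x(rng, batch=2, edge=12):
    return Tensor(rng.random((batch, 1, edge, edge, edge)))


class TestBackboneStructure:
    def test_standard_plan_sixteen_pairs(self):
        bb = build_main_backbone(1, base_width=4)     # narrow, same topology
        assert bb.block_count == 16
        assert len(bb.block_pairs) == 16
        assert bb.block_plan == (3, 4, 6, 3)

    def test_reduced_plan_four_pairs(self, tiny_backbone):
        assert tiny_backbone.block_count == 4

    def test_bad_bottleneck_plan_rejected(self):
        with pytest.raises(ValueError, match="16"):
            build_main_backbone(1, (1, 1, 1, 1), "bottleneck")

    def test_copies_identical_at_init(self, tiny_backbone, rng):
        tiny_backbone.eval()
        x = tiny_backbone.stem(_x(rng))
        with no_grad():
            for pair in tiny_backbone.block_pairs:
                f, t = pair.frozen(x), pair.tuned(x)
                assert np.array_equal(f.data, t.data)
                x = f

    def test_agent_logits_shape(self, tiny_agent, rng):
        for batch in (1, 3):
            out = tiny_agent(_x(rng, batch))
            assert out.shape == (batch, 4, 2)

    def test_agent_head_not_constant(self, tiny_agent, rng):
        tiny_agent.eval()
        with no_grad():
            a = tiny_agent(_x(rng)).data
        assert not np.allclose(a[0], a[1])

    def test_standard_agent_sixteen_by_two(self, rng):
        ag = build_agent(1, 16, base_width=2)
        with no_grad():
            assert ag(_x(rng, 1)).shape == (1, 16, 2)


class TestPolicy:
    def test_no_noise_argmax(self):
        alpha = Tensor(np.array([[[np.log(0.1), np.log(2.0)]]]))
        pol = sample_policy(alpha, tau=1.0,
                            noise=np.zeros((1, 1, 2)))
        assert pol.hard[0, 0] == 1.0      # fine-tune category wins

    def test_symmetric_rows_give_half(self):
        alpha = Tensor(np.zeros((1, 3, 2)))
        for tau in (0.5, 100.0):
            pol = sample_policy(alpha, tau, noise=np.ones((1, 3, 2)))
            assert np.allclose(pol.relaxed.data, 0.5)

    def test_rows_sum_to_one(self, rng):
        alpha = Tensor(rng.normal(size=(5, 16, 2)))
        pol = sample_policy(alpha, 100.0, rng=rng)
        assert np.allclose(pol.relaxed.data.sum(axis=-1), 1.0)

    def test_gumbel_argmax_matches_softmax_identity(self):
        # log-scores (0, 1): P(category 2) = e/(1+e), Monte-Carlo check
        r = np.random.default_rng(42)
        n = 10 ** 5
        g = gumbel_noise((n, 2), r)
        p_hat = ((np.array([0.0, 1.0]) + g).argmax(-1) == 1).mean()
        p_exact = np.e / (1 + np.e)
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_hat - p_exact) < 3 * se

    def test_invalid_temperature(self, rng):
        alpha = Tensor(rng.normal(size=(1, 4, 2)))
        with pytest.raises(ValueError, match="temperature"):
            sample_policy(alpha, 0.0, rng=rng)

    def test_nonfinite_logits_rejected(self, rng):
        alpha = Tensor(np.full((1, 4, 2), np.nan))
        with pytest.raises(ValueError, match="finite"):
            sample_policy(alpha, 1.0, rng=rng)

    def test_per_image_noise_batch_invariant(self):
        a = per_image_gumbel(7, [3], 4, 0)
        b = per_image_gumbel(7, [9, 3, 5], 4, 0)
        assert np.array_equal(a[0], b[1])

    def test_policy_log_csv(self, rng, tmp_path):
        from spottune3d.routing import write_policy_log
        alpha = Tensor(rng.normal(size=(2, 16, 2)))
        pol = sample_policy(alpha, 100.0, rng=rng)
        path = tmp_path / "routes.csv"
        write_policy_log(path, ["P0", "P1"], pol)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "patient_id,route"
        assert len(lines) == 3 and len(lines[1].split(",")[1]) == 16


class TestRoutedForward:
    def test_zero_policy_equals_frozen_forward(self, net, rng):
        net.eval()
        x = _x(rng)
        with no_grad():
            routed, _ = net.forward(x, force_policy=np.zeros(4))
            plain = net.backbone(x).sigmoid()
        assert np.array_equal(routed.data, plain.data)

    def test_one_policy_equals_zero_at_init(self, net, rng):
        net.eval()
        x = _x(rng)
        with no_grad():
            p1, _ = net.forward(x, force_policy=np.ones(4))
            p0, _ = net.forward(x, force_policy=np.zeros(4))
        assert np.array_equal(p1.data, p0.data)

    def test_mixed_batch_equals_independent_passes(self, net, rng):
        net.eval()
        # perturb the tuned copy so the two paths differ
        for _, p in net.backbone.tuned.named_parameters():
            p.data = p.data + 0.01
        xa, xb = _x(rng, 1), _x(rng, 1)
        both = Tensor(np.concatenate([xa.data, xb.data]))
        policy = np.array([[0, 1, 0, 1], [1, 0, 1, 0]], dtype=float)
        with no_grad():
            mixed, _ = net.forward(both, force_policy=policy)
            pa, _ = net.forward(xa, force_policy=policy[0])
            pb, _ = net.forward(xb, force_policy=policy[1])
        assert np.allclose(mixed.data[0], pa.data[0], atol=1e-12)
        assert np.allclose(mixed.data[1], pb.data[0], atol=1e-12)

    def test_probability_in_unit_interval(self, net, rng):
        net.eval()
        with no_grad():
            p, _ = net.forward(_x(rng), rng=rng, mode="eval")
        assert np.all((p.data > 0) & (p.data < 1))

    def test_gradient_reaches_agent(self, net, rng):
        st.apply_freeze_plan(net.backbone, "spottune", net.agent)
        net.train()
        x = _x(rng)
        noise = per_image_gumbel(0, [0, 1], 4, 0)
        prob, _ = net.forward(x, noise=noise, mode="train")
        loss = ((prob - 0.9) ** 2).sum()
        loss.backward()
        gnorm = sum(float(np.abs(p.grad).sum())
                    for p in net.agent.parameters() if p.grad is not None)
        assert gnorm > 0

    def test_tau_limits(self, rng):
        alpha = Tensor(rng.normal(size=(1000, 16, 2)))
        low = sample_policy(alpha, 0.01, rng=np.random.default_rng(1))
        agree = (low.relaxed.data.argmax(-1) == low.argmax).mean()
        assert agree > 0.99
        high = sample_policy(alpha, 1e4, rng=np.random.default_rng(1))
        assert np.abs(high.relaxed.data - 0.5).max() < 1e-3
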