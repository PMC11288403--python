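"""Checkpoint loading, weight inflation, freeze plans."""

import numpy as np
import pytest

import spottune3d as st
from spottune3d.backbones import build_agent, build_main_backbone
from spottune3d.nn import Adam, Tensor, no_grad
from spottune3d.nn.functional import binary_cross_entropy_with_logits
from spottune3d.routing import SpotTuneNetwork, per_image_gumbel
from spottune3d.transfer import (FREEZE_PLANS, apply_freeze_plan,
                                 inflate_weights, load_checkpoint,
                                 load_pretrained, save_checkpoint)


def _medicalnet_style_checkpoint(backbone, prefix=""):
    """Staged layerS.B-named checkpoint matching the backbone layout."""
    state = backbone.state_dict()
    ckpt, plan = {}, backbone.block_plan
    bounds = np.cumsum((0,) + plan)
    for k, v in state.items():
        if k.startswith("frozen."):
            flat_s, rest = k[len("frozen."):].split(".", 1)
            flat = int(flat_s)
            stage = int(np.searchsorted(bounds, flat, side="right"))
            block = flat - bounds[stage - 1]
            ckpt[f"{prefix}layer{stage}.{block}.{rest}"] = v
        elif not k.startswith(("tuned.", "fc.")):
            ckpt[prefix + k] = v
    return ckpt


class TestLoadPretrained:
    def test_round_trip_from_fresh_backbone(self, tmp_path):
        src = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=5)
        ckpt = _medicalnet_style_checkpoint(src, prefix="module.")
        path = save_checkpoint(ckpt, tmp_path / "weights")
        dst = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=9)
        report = load_pretrained(load_checkpoint(path), dst)
        assert not report["ignored"]
        for k, v in src.state_dict().items():
            if not k.startswith("fc."):
                assert np.array_equal(dst.state_dict()[k], v), k

    def test_frozen_equals_tuned_after_load(self):
        src = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=5)
        dst = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=9)
        load_pretrained(_medicalnet_style_checkpoint(src), dst)
        state = dst.state_dict()
        for k in state:
            if k.startswith("frozen."):
                assert np.array_equal(state[k], state["tuned." + k[7:]]), k

    def test_wrong_shaped_stem_raises_with_key(self):
        src = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=5)
        ckpt = _medicalnet_style_checkpoint(src)
        ckpt["conv1.weight"] = np.zeros((4, 1, 3, 3, 3))
        dst = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=9)
        with pytest.raises(ValueError, match="conv1.weight"):
            load_pretrained(ckpt, dst)

    def test_missing_body_key_listed(self):
        src = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=5)
        ckpt = _medicalnet_style_checkpoint(src)
        del ckpt["layer1.0.conv1.weight"]
        dst = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=9)
        with pytest.raises(KeyError, match="0.conv1.weight"):
            load_pretrained(ckpt, dst)


class TestInflation:
    def test_identity_at_one_channel(self, rng):
        w = rng.normal(size=(4, 1, 7, 7, 7))
        assert np.array_equal(inflate_weights(w, 1), w)

    def test_three_channel_duplication(self, rng):
        w = rng.normal(size=(4, 1, 3, 3, 3))
        out = inflate_weights(w, 3)
        assert out.shape == (4, 3, 3, 3, 3)
        for c in range(3):
            assert np.array_equal(out[:, c:c + 1], w / 3)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_channel_replicated_input_linearity(self, rng, n):
        # sum over n channels of (w/n)·x equals w·x to machine precision
        from spottune3d.nn import functional as F
        w = rng.normal(size=(3, 1, 3, 3, 3))
        x = rng.normal(size=(1, 1, 8, 8, 8))
        single = F.conv3d(Tensor(x), Tensor(w), 1, 1).data
        inflated = inflate_weights(w, n)
        xn = np.repeat(x, n, axis=1)
        multi = F.conv3d(Tensor(xn), Tensor(inflated), 1, 1).data
        assert np.allclose(single, multi, atol=1e-12, rtol=0)

    def test_invalid_channel_count(self, rng):
        with pytest.raises(ValueError):
            inflate_weights(rng.normal(size=(2, 1, 3, 3, 3)), 0)


class TestFreezePlans:
    def test_transfer_frozen_only_classifier(self, tiny_backbone):
        manifest = apply_freeze_plan(tiny_backbone, "transfer_frozen")
        assert manifest and all(n.startswith("fc.") for n in manifest)

    def test_random_all_single_network_params(self, tiny_backbone):
        manifest = apply_freeze_plan(tiny_backbone, "random")
        prefixes = {n.split(".")[0] for n in manifest}
        assert prefixes == {"conv1", "bn1", "tuned", "fc"}
        assert not any(n.startswith("frozen.") for n in manifest)

    def test_relaxed_last_two_blocks(self, tiny_backbone):
        manifest = apply_freeze_plan(tiny_backbone, "transfer_relaxed")
        blocks = {n.split(".")[1] for n in manifest if n.startswith("tuned.")}
        assert blocks == {"2", "3"}      # final two of the 4-block plan
        assert any(n.startswith("fc.") for n in manifest)

    def test_unknown_plan_rejected(self, tiny_backbone):
        with pytest.raises(ValueError, match="unknown freeze plan"):
            apply_freeze_plan(tiny_backbone, "everything")

    @pytest.mark.parametrize("plan", FREEZE_PLANS)
    def test_non_trainable_bit_identical_after_steps(self, plan, rng):
        backbone = build_main_backbone(1, (1, 1, 1, 1), "basic", 4, seed=1)
        agent = build_agent(1, 4, base_width=2, seed=1)
        manifest = apply_freeze_plan(backbone, plan, agent)
        before = {n: p.data.copy() for n, p in backbone.named_parameters()}
        before_agent = {n: p.data.copy() for n, p in agent.named_parameters()}
        net = SpotTuneNetwork(backbone, agent, tau=100.0)
        params = list(backbone.parameters()) + list(agent.parameters())
        opt = Adam(params, lr=1e-2)
        backbone.train(True)
        agent.train(plan == "spottune")
        y = np.array([[1.0], [0.0]])
        for step in range(20):
            x = Tensor(rng.random((2, 1, 12, 12, 12)))
            if plan == "spottune":
                noise = per_image_gumbel(0, [0, 1], 4, step)
                logit, _ = net.forward(x, noise=noise, mode="train",
                                       output="logit")
            else:
                logit = backbone.forward_tuned(x)
            loss = binary_cross_entropy_with_logits(logit, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        manifest_set = set(manifest)
        for n, p in backbone.named_parameters():
            if n not in manifest_set:
                assert np.array_equal(p.data, before[n]), (plan, n)
        if plan != "spottune":
            for n, p in agent.named_parameters():
                assert np.array_equal(p.data, before_agent[n]), (plan, n)
        # trainable parameters did move
        moved = any(not np.array_equal(p.data, before[n])
                    for n, p in backbone.named_parameters()
                    if n in manifest_set)
        assert moved
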