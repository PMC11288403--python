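"""Volumetric residual networks.

The main backbone is a 3D ResNet50 — 16 bottleneck residual blocks in four
stages (3, 4, 6, 3) — instantiated as two structurally identical copies: a
frozen copy and a fine-tunable copy, sharing one stem and one classifier
head. The agent is a 3D ResNet10 (four basic blocks) whose head emits one
(frozen vs fine-tune) two-way logit pair per main-network block.

Layer hyperparameters follow the MedicalNet 3D ResNet convention (7³ stem
convolution with stride 2 and pad 3, 3³ max-pool stride 2, bottleneck
expansion 4, same-padding 3³ convolutions) so released checkpoints map
key-for-key through :mod:`spottune3d.transfer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm3d, Conv3d, Linear, MaxPool3d, Module, Sequential,
                 Tensor)
from .nn import functional as F

STANDARD_BLOCK_PLAN = (3, 4, 6, 3)      # ResNet50: 16 bottleneck blocks
AGENT_BLOCK_PLAN = (1, 1, 1, 1)         # ResNet10: 4 basic blocks


class BasicBlock3d(Module):
    expansion = 1

    def __init__(self, in_ch: int, planes: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv3d(in_ch, planes, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm3d(planes)
        self.conv2 = Conv3d(planes, planes, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(planes)
        if stride != 1 or in_ch != planes:
            self.downsample = Sequential(
                Conv3d(in_ch, planes, 1, stride=stride, rng=rng),
                BatchNorm3d(planes))
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = self.downsample(x) if self.downsample is not None else x
        return (out + skip).relu()


class Bottleneck3d(Module):
    expansion = 4

    def __init__(self, in_ch: int, planes: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv3d(in_ch, planes, 1, rng=rng)
        self.bn1 = BatchNorm3d(planes)
        self.conv2 = Conv3d(planes, planes, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(planes)
        self.conv3 = Conv3d(planes, planes * self.expansion, 1, rng=rng)
        self.bn3 = BatchNorm3d(planes * self.expansion)
        if stride != 1 or in_ch != planes * self.expansion:
            self.downsample = Sequential(
                Conv3d(in_ch, planes * self.expansion, 1, stride=stride, rng=rng),
                BatchNorm3d(planes * self.expansion))
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        skip = self.downsample(x) if self.downsample is not None else x
        return (out + skip).relu()


def _make_stage(block_cls, in_ch, planes, n_blocks, stride, rng):
    blocks = [block_cls(in_ch, planes, stride, rng=rng)]
    out_ch = planes * block_cls.expansion
    for _ in range(n_blocks - 1):
        blocks.append(block_cls(out_ch, planes, 1, rng=rng))
    return blocks, out_ch


@dataclass
class RoutedBlockPair:
    """One routed position: the frozen block and its fine-tunable twin."""
    frozen: Module
    tuned: Module
    index: int          # 1-based block index


class MainBackbone(Module):
    """Two parallel residual stacks behind a shared stem and classifier.

    ``frozen`` holds the non-trainable copy; ``tuned`` is a structurally
    identical, initially value-identical copy that training may adjust.
    The classifier is a global average pool into a single logit (sigmoid
    probability downstream).
    """

    def __init__(self, in_channels: int = 1,
                 block_plan: tuple[int, ...] = STANDARD_BLOCK_PLAN,
                 block: str = "bottleneck", base_width: int = 64,
                 seed: int = 0):
        super().__init__()
        block_cls = {"bottleneck": Bottleneck3d, "basic": BasicBlock3d}[block]
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.block_plan = tuple(block_plan)
        self.block_type = block
        self.base_width = base_width
        self.conv1 = Conv3d(in_channels, base_width, 7, stride=2, padding=3,
                            rng=rng)
        self.bn1 = BatchNorm3d(base_width)
        self.maxpool = MaxPool3d(3, 2, 1)

        frozen_blocks = []
        ch = base_width
        for i, n in enumerate(block_plan):
            planes = base_width * (2 ** i)
            stage, ch = _make_stage(block_cls, ch, planes, n,
                                    1 if i == 0 else 2, rng)
            frozen_blocks.extend(stage)
        self.frozen = Sequential(*frozen_blocks)
        # the tuned copy: identical structure, then identical values
        rng2 = np.random.default_rng(seed)  # same init stream -> same shapes
        tuned_blocks = []
        ch = base_width
        for i, n in enumerate(block_plan):
            planes = base_width * (2 ** i)
            stage, ch = _make_stage(block_cls, ch, planes, n,
                                    1 if i == 0 else 2, rng2)
            tuned_blocks.extend(stage)
        self.tuned = Sequential(*tuned_blocks)
        self.tuned.load_state_dict(self.frozen.state_dict())
        self.feature_dim = ch
        self.fc = Linear(ch, 1, rng=rng)
        self.freeze_frozen_copy()

    # ------------------------------------------------------------------ api
    @property
    def block_count(self) -> int:
        return sum(self.block_plan)

    @property
    def block_pairs(self) -> list[RoutedBlockPair]:
        return [RoutedBlockPair(f, t, i + 1)
                for i, (f, t) in enumerate(zip(self.frozen, self.tuned))]

    def freeze_frozen_copy(self):
        # frozen copy always runs in inference mode: running statistics are
        # never updated, preserving strict "frozen" semantics
        self.frozen.requires_grad_(False)
        self.frozen._always_eval = True
        self.frozen.train(False)

    def stem(self, x: Tensor) -> Tensor:
        return self.maxpool(self.bn1(self.conv1(x)).relu())

    def head(self, feat: Tensor) -> Tensor:
        """Pooled features -> single logit."""
        return self.fc(F.global_avg_pool(feat))

    def forward(self, x: Tensor) -> Tensor:
        """Plain forward through the frozen stack (logit output)."""
        h = self.stem(x)
        for blk in self.frozen:
            h = blk(h)
        return self.head(h)

    def forward_tuned(self, x: Tensor) -> Tensor:
        """Plain forward through the tuned stack (logit output); this is
        the single-ResNet path the non-routed comparison plans use."""
        h = self.stem(x)
        for blk in self.tuned:
            h = blk(h)
        return self.head(h)


class AgentNet(Module):
    """3D ResNet10 policy network: emits (block_count × 2) routing logits
    per input image, consuming the same preprocessed volume as the main
    network."""

    def __init__(self, in_channels: int = 1, block_count: int = 16,
                 base_width: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 1)
        self.block_count = block_count
        self.conv1 = Conv3d(in_channels, base_width, 7, stride=2, padding=3,
                            rng=rng)
        self.bn1 = BatchNorm3d(base_width)
        self.maxpool = MaxPool3d(3, 2, 1)
        blocks = []
        ch = base_width
        for i, n in enumerate(AGENT_BLOCK_PLAN):
            planes = base_width * (2 ** i)
            stage, ch = _make_stage(BasicBlock3d, ch, planes, n,
                                    1 if i == 0 else 2, rng)
            blocks.extend(stage)
        self.layers = Sequential(*blocks)
        self.fc = Linear(ch, block_count * 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.maxpool(self.bn1(self.conv1(x)).relu())
        h = self.layers(h)
        logits = self.fc(F.global_avg_pool(h))
        return logits.reshape(x.shape[0], self.block_count, 2)


def build_main_backbone(in_channels: int = 1,
                        block_plan: tuple[int, ...] | None = None,
                        block: str = "bottleneck", base_width: int = 64,
                        seed: int = 0) -> MainBackbone:
    """Standard call (no plan) gives the 16-block bottleneck ResNet50."""
    plan = tuple(block_plan) if block_plan is not None else STANDARD_BLOCK_PLAN
    if block == "bottleneck" and sum(plan) != 16:
        raise ValueError(
            f"the standard bottleneck plan must sum to 16 blocks, got {plan}")
    return MainBackbone(in_channels, plan, block, base_width, seed)


def build_agent(in_channels: int = 1, block_count: int = 16,
                base_width: int = 64, seed: int = 0) -> AgentNet:
    return AgentNet(in_channels, block_count, base_width, seed)
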