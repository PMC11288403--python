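"""Gumbel-Softmax dynamic routing with straight-through gradients.

For every input image the agent emits a pair of category scores per main
block. A shared standard-Gumbel perturbation G gives both the hard sample

    X = argmax_c [log α̃_c + G_c]

and its temperature-τ relaxation

    Y_c = exp((log α̃_c + G_c)/τ) / Σ_j exp((log α̃_j + G_j)/τ),

where α̃ is the softmax of the agent's raw scores (so the logs are always
defined). The routed residual update for block ℓ is

    x_ℓ = I_ℓ(x) · F̂_ℓ(x_{ℓ-1}) + (1 − I_ℓ(x)) · F_ℓ(x_{ℓ-1}),

with each block carrying its own skip path (identity, or the standard
strided projection on stage boundaries). The exposed policy value I equals
the hard sample while its gradient is that of the relaxed Y (straight-
through estimator), so back-propagation reaches the agent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbones import AgentNet, MainBackbone, RoutedBlockPair
from .nn import Tensor

FINE_TUNE = 1       # category index meaning "use the fine-tuned block"


@dataclass
class RoutingPolicy:
    """Per-image binary routing decisions and their relaxed counterpart."""
    hard: np.ndarray            # (B, L) in {0,1}; 1 = fine-tuned path
    argmax: np.ndarray          # (B, L) the Gumbel-argmax category sample
    relaxed: Tensor             # (B, L, 2) rows summing to 1
    straight_through: Tensor    # (B, L) = hard in value, relaxed in gradient

    def routing_strings(self) -> list[str]:
        """One '0'/'1' string per image (loggable per patient)."""
        return ["".join(str(int(b)) for b in row) for row in self.hard]


def write_policy_log(path, patient_ids: list[str],
                     policy: "RoutingPolicy") -> None:
    """Log per-patient routing strings as CSV (patient_id, route).

    Every patient's unique route through the frozen/fine-tuned blocks is
    the interpretable artifact of the adaptive fine-tuning."""
    import csv

    strings = policy.routing_strings()
    if len(strings) != len(patient_ids):
        raise ValueError("one policy row per patient id required")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "route"])
        w.writerows(zip(patient_ids, strings))


def gumbel_noise(shape, rng: np.random.Generator) -> np.ndarray:
    """Standard Gumbel draws G = -log(-log U), U ~ uniform(0,1)."""
    u = rng.random(shape)
    tiny = np.finfo(np.float64).tiny
    return -np.log(-np.log(np.clip(u, tiny, 1.0 - 1e-16)))


def per_image_gumbel(seed: int, image_keys, n_blocks: int,
                     sample_index: int = 0) -> np.ndarray:
    """Counter-based per-image Gumbel draws: each image's noise depends only
    on (seed, its own key, sample_index), not on batch composition."""
    rows = []
    for key in image_keys:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(key), int(sample_index)]))
        rows.append(gumbel_noise((n_blocks, 2), rng))
    return np.stack(rows)


def sample_policy(alpha: Tensor, tau: float,
                  rng: np.random.Generator | None = None,
                  noise: np.ndarray | None = None) -> RoutingPolicy:
    """Draw a routing policy from agent logits ``alpha`` of shape (B, L, 2).

    One shared noise draw G serves both the hard argmax sample and the
    relaxed softmax value, as the straight-through contract requires.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    if not np.all(np.isfinite(alpha.data)):
        raise ValueError("non-finite agent logits")
    alpha_tilde = alpha.softmax(axis=-1)
    log_alpha = alpha_tilde.log()
    if noise is None:
        if rng is None:
            raise ValueError("either rng or noise must be given")
        noise = gumbel_noise(alpha.shape, rng)
    scores = log_alpha + Tensor(noise)
    argmax = scores.data.argmax(axis=-1)
    hard = (argmax == FINE_TUNE).astype(np.float64)
    relaxed = (scores * (1.0 / tau)).softmax(axis=-1)
    y_ft = relaxed[:, :, FINE_TUNE]
    straight = Tensor(hard) + (y_ft - y_ft.detach())
    return RoutingPolicy(hard=hard, argmax=argmax, relaxed=relaxed,
                         straight_through=straight)


def route_forward(x_prev: Tensor, pair: RoutedBlockPair, indicator) -> Tensor:
    """Blend the frozen and fine-tuned block outputs per image.

    ``indicator`` is a scalar, an array of shape (B,), or a Tensor carrying
    straight-through gradients; each image in the batch follows its own
    binary decision.
    """
    if not isinstance(indicator, Tensor):
        indicator = Tensor(np.asarray(indicator, dtype=np.float64))
    B = x_prev.shape[0]
    ind = indicator.reshape((B,) + (1,) * (x_prev.ndim - 1)) \
        if indicator.ndim == 1 else indicator
    i_data = np.asarray(ind.data).reshape(-1)
    if i_data.size == B and np.all(i_data == 0.0) and not ind.requires_grad \
            and not ind._parents:
        return pair.frozen(x_prev)
    if i_data.size == B and np.all(i_data == 1.0) and not ind.requires_grad \
            and not ind._parents:
        return pair.tuned(x_prev)
    out_tuned = pair.tuned(x_prev)
    out_frozen = pair.frozen(x_prev)
    return ind * out_tuned + (1.0 - ind) * out_frozen


class SpotTuneNetwork:
    """Agent + routed main backbone, evaluated as one classifier."""

    def __init__(self, backbone: MainBackbone, agent: AgentNet,
                 tau: float = 100.0):
        if agent.block_count != backbone.block_count:
            raise ValueError(
                f"agent emits {agent.block_count} decisions but backbone has "
                f"{backbone.block_count} blocks")
        self.backbone = backbone
        self.agent = agent
        self.tau = tau

    def train(self, mode: bool = True):
        self.backbone.train(mode)
        self.agent.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                noise: np.ndarray | None = None,
                force_policy: np.ndarray | None = None,
                mode: str = "train",
                output: str = "prob") -> tuple[Tensor, RoutingPolicy | None]:
        """Full pass: agent → policy → routed main network → probability.

        ``mode='train'`` uses straight-through indicators so gradients reach
        the agent; ``mode='eval'`` follows the hard stochastic policy only.
        ``force_policy`` bypasses the agent entirely (e.g. all-zero for the
        pure frozen path).
        """
        if force_policy is not None:
            fp = np.asarray(force_policy, dtype=np.float64)
            if fp.ndim == 1:
                fp = np.broadcast_to(fp, (x.shape[0], fp.shape[0]))
            h = self.backbone.stem(x)
            for k, pair in enumerate(self.backbone.block_pairs):
                h = route_forward(h, pair, fp[:, k])
            logit = self.backbone.head(h)
            return (logit if output == "logit" else logit.sigmoid()), None

        alpha = self.agent(x)
        policy = sample_policy(alpha, self.tau, rng=rng, noise=noise)
        h = self.backbone.stem(x)
        if mode == "train":
            for k, pair in enumerate(self.backbone.block_pairs):
                h = route_forward(h, pair, policy.straight_through[:, k])
        else:
            for k, pair in enumerate(self.backbone.block_pairs):
                h = route_forward(h, pair, policy.hard[:, k])
        logit = self.backbone.head(h)
        return (logit if output == "logit" else logit.sigmoid()), policy

    __call__ = forward
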