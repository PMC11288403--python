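"""Training loop, selection criterion M, and model selection.

Defaults mirror the study protocol: at most 90 epochs, batch size 12,
starting learning rates 1e-5 (main network) and 1e-4 (agent), one shared
reduce-on-plateau schedule on validation loss (patience 20 epochs, factor
0.1), Gumbel-Softmax temperature 100, binary cross-entropy loss, Adam.

Model selection uses the criterion

    M = 0.6·[SEN ≥ 0.5] + 0.4·[SPE ≥ 0.5]

with inclusive thresholds; among epochs with M = 1.0 on validation the one
with the highest validation AUC is chosen (ties to the earliest epoch), and
if no epoch passes, the final epoch's model is used and flagged as a
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import AgentNet, MainBackbone
from .nn import Adam, ReduceLROnPlateau, Tensor, no_grad
from .nn.functional import binary_cross_entropy_with_logits
from .routing import SpotTuneNetwork, per_image_gumbel
from .sampling import Sample


@dataclass
class TrainConfig:
    max_epochs: int = 90
    batch_size: int = 12
    lr_main: float = 1e-5
    lr_agent: float = 1e-4
    scheduler_patience: int = 20
    scheduler_factor: float = 0.1
    tau: float = 100.0
    seed: int = 0

    def validate(self):
        if self.lr_main < 0 or self.lr_agent < 0:
            raise ValueError("learning rates must be >= 0")
        if self.scheduler_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def selection_metric(sen: float, spe: float) -> float:
    """Criterion M = 0.6·[SEN ≥ 0.5] + 0.4·[SPE ≥ 0.5] (inclusive)."""
    if not (0.0 <= sen <= 1.0 and 0.0 <= spe <= 1.0):
        raise ValueError(
            f"SEN and SPE must lie in [0,1], got SEN={sen}, SPE={spe}")
    return 0.6 * (sen >= 0.5) + 0.4 * (spe >= 0.5)


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_loss: float
    val_auc: float
    val_ap: float
    val_sen: float
    val_spe: float
    val_m: float
    lr_main: float
    state: dict = field(default_factory=dict, repr=False)


@dataclass
class TrainResult:
    log: list[EpochLog]
    chosen_epoch: int
    fallback: bool
    best_state: dict


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack(samples: list[Sample], idx) -> tuple[np.ndarray, np.ndarray, list]:
    x = np.stack([samples[i].volume for i in idx])[:, None]  # (B,1,D,H,W)
    y = np.array([samples[i].label for i in idx], dtype=np.float64)
    keys = [i for i in idx]
    return x, y, keys


def _forward_plan(backbone: MainBackbone, net: SpotTuneNetwork | None,
                  plan: str, x: Tensor, noise=None):
    """Training-mode logits under the given freeze plan."""
    if plan == "spottune":
        logit, _ = net.forward(x, noise=noise, mode="train", output="logit")
        return logit
    return backbone.forward_tuned(x)


def predict_probabilities(backbone: MainBackbone, plan: str,
                          samples: list[Sample],
                          net: SpotTuneNetwork | None = None,
                          noise_seed: int = 0, sample_index: int = 0,
                          batch_size: int = 8) -> np.ndarray:
    """Eval-mode positive-class probabilities, one stochastic policy per
    image for the spottune plan (per-image counter-based Gumbel streams)."""
    backbone.train(False)
    if net is not None:
        net.eval()
    probs = []
    with no_grad():
        for start in range(0, len(samples), batch_size):
            idx = list(range(start, min(start + batch_size, len(samples))))
            x, _, keys = _stack(samples, idx)
            xt = Tensor(x)
            if plan == "spottune":
                noise = per_image_gumbel(noise_seed, keys,
                                         backbone.block_count, sample_index)
                p, _ = net.forward(xt, noise=noise, mode="eval")
                probs.append(p.data.reshape(-1))
            else:
                probs.append(
                    backbone.forward_tuned(xt).sigmoid().data.reshape(-1))
    return np.concatenate(probs)


def train_fold(train_samples: list[Sample], val_samples: list[Sample],
               backbone: MainBackbone, plan: str,
               agent: AgentNet | None = None,
               config: TrainConfig | None = None,
               keep_states: bool = True) -> TrainResult:
    """Train one CV fold under a freeze plan and select the best epoch.

    The training set is expected to be augmented and class-balanced; the
    validation set is untouched (imbalance kept). Deterministic given the
    config seed.
    """
    from .evaluation import compute_metrics  # local import: cycle avoidance

    cfg = config or TrainConfig()
    cfg.validate()
    if not train_samples or not val_samples:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(cfg.seed)
    net = SpotTuneNetwork(backbone, agent, cfg.tau) \
        if plan == "spottune" else None

    main_params = [p for _, p in backbone.named_parameters()]
    opts = [Adam([p for p in main_params], lr=cfg.lr_main)]
    if plan == "spottune":
        opts.append(Adam(list(agent.parameters()), lr=cfg.lr_agent))
    sched = ReduceLROnPlateau(opts, cfg.scheduler_patience,
                              cfg.scheduler_factor)
    val_y = np.array([s.label for s in val_samples], dtype=np.float64)

    log: list[EpochLog] = []
    for epoch in range(1, cfg.max_epochs + 1):
        backbone.train(True)
        if agent is not None:
            agent.train(plan == "spottune")
        losses = []
        for batch_idx, idx in enumerate(
                _batches(len(train_samples), cfg.batch_size, rng)):
            x, y, keys = _stack(train_samples, idx)
            xt = Tensor(x)
            noise = None
            if plan == "spottune":
                noise = per_image_gumbel(cfg.seed, keys,
                                         backbone.block_count,
                                         sample_index=epoch * 100003 + batch_idx)
            logit = _forward_plan(backbone, net, plan, xt, noise)
            loss = binary_cross_entropy_with_logits(logit, y.reshape(-1, 1))
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            for opt in opts:
                opt.zero_grad()
            loss.backward()
            for opt in opts:
                opt.step()
            losses.append(loss.item())

        val_p = predict_probabilities(backbone, plan, val_samples, net,
                                      noise_seed=cfg.seed,
                                      sample_index=epoch,
                                      batch_size=cfg.batch_size)
        eps = 1e-12
        val_loss = float(-np.mean(
            val_y * np.log(val_p + eps) + (1 - val_y) * np.log(1 - val_p + eps)))
        m = compute_metrics(val_p, val_y)
        state = {}
        if keep_states:
            state = backbone.state_dict()
            if agent is not None:
                state.update({"agent." + k: v
                              for k, v in agent.state_dict().items()})
        log.append(EpochLog(epoch, float(np.mean(losses)), val_loss,
                            m.auc, m.ap, m.sen, m.spe, m.m,
                            opts[0].lr, state))
        sched.step(val_loss)

    chosen, fallback = select_model(log)
    return TrainResult(log=log, chosen_epoch=chosen.epoch, fallback=fallback,
                       best_state=chosen.state)


def select_model(log: list[EpochLog]) -> tuple[EpochLog, bool]:
    """Among epochs with validation M = 1.0, take the highest validation
    AUC (earliest epoch on ties); otherwise fall back to the final epoch."""
    if not log:
        raise ValueError("empty epoch log")
    passing = [e for e in log if e.val_m == 1.0]
    if passing:
        best = max(passing, key=lambda e: (e.val_auc, -e.epoch))
        return best, False
    return log[-1], True
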