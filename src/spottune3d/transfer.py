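"""Checkpoint ingestion, weight inflation, and freeze plans.

Checkpoints are flat name→array maps saved with ``numpy.savez``. The key
schema mirrors the MedicalNet/torchvision 3D ResNet naming
(``conv1.weight``, ``bn1.*``, ``layerS.B.convK.weight`` ...); an adapter
strips foreign prefixes (``module.``, ``state_dict.``) and maps staged
``layerS.B`` names onto the backbone's flat block indices for both the
frozen and the fine-tunable copy.

Four freeze plans are supported:

* ``spottune``        — frozen copy fixed; tuned copy, agent and classifier train
* ``random``          — no checkpoint; everything trains from fresh uniform init
* ``transfer_frozen`` — transferred weights; only the classifier trains
* ``transfer_relaxed``— transferred weights; classifier plus the last two
  residual blocks train
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .backbones import AgentNet, MainBackbone

FREEZE_PLANS = ("spottune", "random", "transfer_frozen", "transfer_relaxed")

_HEAD_PREFIXES = ("fc.",)          # classifier keys may be absent in a checkpoint
_FOREIGN_PREFIXES = ("module.", "state_dict.")


def save_checkpoint(state: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    np.savez(path.with_suffix(".npz") if path.suffix != ".npz" else path,
             **state)
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as z:
        return {k: z[k].copy() for k in z.files}


def _strip_prefix(key: str) -> str:
    changed = True
    while changed:
        changed = False
        for p in _FOREIGN_PREFIXES:
            if key.startswith(p):
                key = key[len(p):]
                changed = True
    return key


def _layer_to_flat(key: str, block_plan: tuple[int, ...]) -> str | None:
    """Map 'layerS.B.rest' to a flat block index string 'N.rest'."""
    if not key.startswith("layer"):
        return None
    stage_s, block_s, rest = key.split(".", 2)
    stage = int(stage_s[len("layer"):]) - 1
    flat = sum(block_plan[:stage]) + int(block_s)
    return f"{flat}.{rest}"


def load_pretrained(checkpoint: dict[str, np.ndarray] | str | Path,
                    backbone: MainBackbone) -> dict[str, list[str]]:
    """Initialize both the frozen and the tuned copy from one checkpoint.

    Classifier (and agent) keys absent from the checkpoint stay at their
    fresh initialization. Returns a report of matched/ignored keys.
    Shape mismatches and missing non-head keys raise with the key names.
    """
    if not isinstance(checkpoint, dict):
        checkpoint = load_checkpoint(checkpoint)
    own = dict(backbone.named_parameters())
    own.update(dict(backbone.named_buffers()))

    matched, ignored = [], []
    staged = {}
    for raw_key, value in checkpoint.items():
        key = _strip_prefix(raw_key)
        targets = []
        flat = _layer_to_flat(key, backbone.block_plan)
        if flat is not None:
            targets = [f"frozen.{flat}", f"tuned.{flat}"]
        elif key.startswith(("frozen.", "tuned.")):
            targets = [key]
        elif key.startswith(_HEAD_PREFIXES) and key in own:
            targets = [key]
        elif key in own:                       # stem keys: conv1/bn1
            targets = [key]
        else:
            ignored.append(raw_key)
            continue
        for t in targets:
            if t not in own:
                ignored.append(raw_key)
                continue
            tgt_shape = own[t].data.shape if hasattr(own[t], "data") \
                else own[t].shape
            if tgt_shape != value.shape:
                raise ValueError(
                    f"shape mismatch for checkpoint key '{raw_key}' -> '{t}': "
                    f"{value.shape} vs {tgt_shape}")
            staged[t] = np.asarray(value, dtype=np.float64)
            matched.append(t)

    # every non-head model key must be covered (frozen/tuned bodies + stem)
    missing = [k for k in own
               if k not in staged and not k.startswith(_HEAD_PREFIXES)]
    if missing:
        raise KeyError(
            f"checkpoint does not cover required keys: {sorted(missing)[:8]}"
            f"{' ...' if len(missing) > 8 else ''}")
    params = dict(backbone.named_parameters())
    buffers = dict(backbone.named_buffers())
    for t, v in staged.items():
        if t in params:
            params[t].data = v.copy()
        else:
            buffers[t][...] = v
    backbone.freeze_frozen_copy()
    return {"matched": matched, "ignored": ignored}


def inflate_weights(stem_weights: np.ndarray, n_channels: int) -> np.ndarray:
    """Adapt a single-channel first-layer kernel to ``n_channels`` inputs.

    The kernel is duplicated n times along the input-channel axis and each
    replica is divided by n, so an input whose channels are identical copies
    of one image produces exactly the single-channel response.
    """
    if n_channels < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels}")
    w = np.asarray(stem_weights)
    if w.ndim != 5 or w.shape[1] != 1:
        raise ValueError(
            f"expected a single-channel conv kernel (Cout, 1, k, k, k), "
            f"got shape {w.shape}")
    return np.repeat(w, n_channels, axis=1) / n_channels


def apply_freeze_plan(backbone: MainBackbone, plan: str,
                      agent: AgentNet | None = None) -> list[str]:
    """Set trainability flags per plan; returns the trainable-name manifest.

    The stem is transferred and kept frozen in every transferred plan
    (spottune / transfer_frozen / transfer_relaxed); under ``random`` all
    parameters train.
    """
    if plan not in FREEZE_PLANS:
        raise ValueError(f"unknown freeze plan '{plan}'; "
                         f"choose from {FREEZE_PLANS}")
    for _, p in backbone.named_parameters():
        p.requires_grad = False
    if agent is not None:
        agent.requires_grad_(plan == "spottune")
    # reset inference-mode pins; the frozen copy is always pinned
    for blk in backbone.tuned:
        blk._always_eval = False
    backbone.bn1._always_eval = False
    backbone.freeze_frozen_copy()

    n_blocks = backbone.block_count
    trainable_prefixes: list[str]
    if plan == "random":
        # the single plain ResNet50: stem + tuned stack + classifier
        trainable_prefixes = ["conv1.", "bn1.", "tuned.", "fc."]
    elif plan == "spottune":
        trainable_prefixes = ["tuned.", "fc."]
        backbone.bn1._always_eval = True       # transferred stem stays fixed
    elif plan == "transfer_frozen":
        trainable_prefixes = ["fc."]
        backbone.bn1._always_eval = True
        for blk in backbone.tuned:
            blk._always_eval = True
    else:  # transfer_relaxed: classifier plus the final two residual blocks
        trainable_prefixes = ["fc.", f"tuned.{n_blocks - 2}.",
                              f"tuned.{n_blocks - 1}."]
        backbone.bn1._always_eval = True
        for blk in list(backbone.tuned)[:-2]:
            blk._always_eval = True

    manifest = []
    for name, p in backbone.named_parameters():
        if any(name.startswith(t) for t in trainable_prefixes):
            p.requires_grad = True
            manifest.append(name)
    backbone.train(backbone.training)          # re-propagate eval pins
    if agent is not None and plan == "spottune":
        manifest += ["agent." + n for n, _ in agent.named_parameters()]
    return manifest
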