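"""Self-contained reduced-scale experiment recipes.

These compose the library's pieces into the study's workflow at desk scale:
simulate a phantom cohort, preprocess, split with a DSC-anchored common
test set, pre-train a source model to serve as the transferred checkpoint,
train per CV fold under a freeze plan, and evaluate the fold ensemble with
the stochastic-policy protocol. They exist so that tests, examples and the
acceptance script all exercise one canonical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .backbones import build_agent, build_main_backbone
from .evaluation import (EvalResult, compute_metrics, ensemble_mean,
                         stochastic_eval)
from .preprocess import PreprocessConfig, preprocess_volume
from .routing import SpotTuneNetwork
from .sampling import (AugmentConfig, Sample, SplitPlan, augment_fold,
                       balance_by_pruning, make_cv_folds, split_cohort)
from .training import TrainConfig, predict_probabilities, train_fold
from .transfer import apply_freeze_plan, load_pretrained
from .volume_io import MRVolume, SegmentationMask


@dataclass
class ReducedExperimentConfig:
    """Desk-scale study conditions: a 60-patient cohort of 32³ volumes with
    a class shift of five background noise standard deviations in the
    enhancing rim, preprocessed by the standard chain down to 14³, learned
    by the reduced 4-block backbone."""

    n_patients: int = 60
    volume_shape: tuple = (32, 32, 32)
    noise_sd: float = 0.1
    effect_multiple: float = 5.0        # effect_size = multiple × noise_sd
    modality: str = "T1"
    crop_shape: tuple = (28, 28, 28)
    downscale_factor: int = 2
    target_slice_edge: int = 14
    base_width: int = 8
    agent_width: int = 4
    block_plan: tuple = (1, 1, 1, 1)
    fold_count: int = 5
    max_epochs: int = 20
    batch_size: int = 8
    lr_main: float = 1e-3
    lr_agent: float = 1e-3
    tau: float = 100.0
    pretrain_epochs: int = 15
    pretrain_lr: float = 3e-3
    eval_samples: int = 50
    eval_seed: int = 42
    augment: bool = True

    @property
    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(self.crop_shape, self.downscale_factor,
                                self.target_slice_edge)


def cohort_samples(cfg: ReducedExperimentConfig, seed: int):
    """Generate, preprocess and split a phantom cohort.

    Returns (split, make) where make(ids) materializes preprocessed
    training samples for the configured modality.
    """
    spec = synthetic.CohortSpec.small(
        n_total=cfg.n_patients, shape=cfg.volume_shape,
        effect_size=cfg.effect_multiple * cfg.noise_sd,
        noise_sd=cfg.noise_sd, seed=seed)
    cohort = synthetic.generate_cohort(spec)
    split = split_cohort(cohort.records, SplitPlan(seed=seed))
    pcfg = cfg.preprocess_config

    def make(ids: list[str]) -> list[Sample]:
        out = []
        for pid in ids:
            rec = cohort.record(pid)
            vol = MRVolume(cohort.volume(pid, cfg.modality), (1, 1, 1),
                           cfg.modality, pid)
            mask = SegmentationMask(cohort.mask(pid))
            v = preprocess_volume(vol, mask, pcfg)
            out.append(Sample(volume=v.voxels, label=rec.label,
                              patient_id=pid))
        return out

    return split, make


def pretrain_source_checkpoint(cfg: ReducedExperimentConfig,
                               seed: int) -> dict[str, np.ndarray]:
    """Train a plain backbone on an independent source phantom cohort and
    export it as a transferable checkpoint (the synthetic stand-in for a
    released pretrained model)."""
    split, make = cohort_samples(cfg, seed)
    train_s = make(split.train["structural"])
    if cfg.augment:
        train_s = augment_fold(train_s, AugmentConfig(seed=seed))
    train_s = balance_by_pruning(train_s, seed=seed)
    bb = build_main_backbone(1, cfg.block_plan, "basic", cfg.base_width,
                             seed=seed)
    apply_freeze_plan(bb, "random")
    tcfg = TrainConfig(max_epochs=cfg.pretrain_epochs,
                       batch_size=cfg.batch_size, lr_main=cfg.pretrain_lr,
                       scheduler_patience=cfg.pretrain_epochs - 1, seed=seed)
    train_fold(train_s, make(split.test), bb, "random", None, tcfg,
               keep_states=False)
    ckpt: dict[str, np.ndarray] = {}
    for k, v in bb.state_dict().items():
        if k.startswith("tuned."):
            ckpt["frozen." + k[6:]] = v
            ckpt[k] = v
        elif k.startswith(("conv1.", "bn1.")):
            ckpt[k] = v
    return ckpt


def run_reduced_experiment(seed: int,
                           cfg: ReducedExperimentConfig | None = None,
                           plan: str = "spottune",
                           checkpoint: dict | None = None) -> EvalResult:
    """One full reduced run: pretrain (unless a checkpoint is given), train
    per CV fold, ensemble fold probabilities, evaluate on the common test
    set. Deterministic given the seed."""
    cfg = cfg or ReducedExperimentConfig()
    if checkpoint is None and plan != "random":
        checkpoint = pretrain_source_checkpoint(cfg, seed + 1000)
    split, make = cohort_samples(cfg, seed)
    test_s = make(split.test)
    labels = np.array([s.label for s in test_s])
    folds = make_cv_folds(split.train["structural"], cfg.fold_count, seed)

    fold_probs = []
    for k in range(cfg.fold_count):
        train_ids = [p for j, f in enumerate(folds) if j != k for p in f]
        train_s = make(train_ids)
        if cfg.augment:
            train_s = augment_fold(train_s,
                                   AugmentConfig(seed=seed * 10 + k))
        train_s = balance_by_pruning(train_s, seed=seed * 10 + k)
        val_s = make(folds[k])
        bb = build_main_backbone(1, cfg.block_plan, "basic", cfg.base_width,
                                 seed=seed * 10 + k)
        agent = build_agent(1, bb.block_count, cfg.agent_width,
                            seed=seed * 10 + k) if plan == "spottune" else None
        if checkpoint is not None and plan != "random":
            load_pretrained(checkpoint, bb)
        apply_freeze_plan(bb, plan, agent)
        tcfg = TrainConfig(max_epochs=cfg.max_epochs,
                           batch_size=cfg.batch_size, lr_main=cfg.lr_main,
                           lr_agent=cfg.lr_agent, tau=cfg.tau,
                           scheduler_patience=cfg.max_epochs - 1,
                           seed=seed * 10 + k)
        train_fold(train_s, val_s, bb, plan, agent, tcfg, keep_states=False)
        if plan == "spottune":
            net = SpotTuneNetwork(bb, agent, cfg.tau)

            def predict(s_idx, rseed, _bb=bb, _net=net, _t=test_s):
                return predict_probabilities(_bb, "spottune", _t, _net,
                                             noise_seed=rseed,
                                             sample_index=s_idx)

            ev = stochastic_eval(predict, labels, cfg.eval_samples,
                                 cfg.eval_seed)
        else:
            ev = compute_metrics(
                predict_probabilities(bb, plan, test_s), labels)
        fold_probs.append(ev.probabilities)
    return compute_metrics(ensemble_mean(fold_probs), labels)
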