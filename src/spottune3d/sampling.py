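"""Cohort splitting, cross-validation folds, augmentation, class balancing.

The train/test split is anchored on the smallest (DSC) modality subset:
the common test set is drawn from patients that have every modality, so
results are directly comparable across modality groups; each modality's
training set is its own patient pool minus that shared test set. The class
imbalance is kept in validation and test sets; only the augmented training
folds are balanced, by random pruning of the majority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, rotate, zoom

from .synthetic import PatientRecord


@dataclass
class SplitPlan:
    test_fraction: float = 0.30
    anchor_modality: str = "dsc"
    fold_count: int = 5
    stratify: bool = True
    seed: int = 0

    def validate(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.fold_count < 2:
            raise ValueError("fold_count must be >= 2")


@dataclass
class CohortSplit:
    train: dict[str, list[str]]     # modality group -> patient ids
    test: list[str]                 # common test set (all modalities)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_cohort(records: list[PatientRecord], plan: SplitPlan) -> CohortSplit:
    """70:30-style split with a common test set from the anchor subset.

    Test size is round-half-up(test_fraction × |anchor subset|); with
    stratification the per-class quotas are apportioned by largest
    remainder so they sum exactly to the test size.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    pools = {
        "structural": [r for r in records],
        "dti": [r for r in records if r.has_dti],
        "dsc": [r for r in records if r.has_dsc],
    }
    anchor = pools[plan.anchor_modality]
    if not anchor:
        raise ValueError(f"empty anchor subset '{plan.anchor_modality}'")
    n_test = _round_half_up(plan.test_fraction * len(anchor))

    if plan.stratify:
        pos = [r.patient_id for r in anchor if r.label == 1]
        neg = [r.patient_id for r in anchor if r.label == 0]
        quota = {}
        exact = {"pos": plan.test_fraction * len(pos),
                 "neg": plan.test_fraction * len(neg)}
        base = {k: int(math.floor(v)) for k, v in exact.items()}
        rem = n_test - sum(base.values())
        order = sorted(exact, key=lambda k: exact[k] - base[k], reverse=True)
        for k in order:
            quota[k] = base[k] + (1 if rem > 0 else 0)
            rem -= 1 if rem > 0 else 0
        test = (list(rng.choice(pos, size=quota["pos"], replace=False)) +
                list(rng.choice(neg, size=quota["neg"], replace=False)))
    else:
        ids = [r.patient_id for r in anchor]
        test = list(rng.choice(ids, size=n_test, replace=False))
    test_set = set(test)
    train = {g: [r.patient_id for r in pool if r.patient_id not in test_set]
             for g, pool in pools.items()}
    return CohortSplit(train=train, test=sorted(test_set))


def make_cv_folds(train_ids: list[str], fold_count: int, seed: int,
                  labels: dict[str, int] | None = None) -> list[list[str]]:
    """Shuffle-partition into folds whose sizes differ by at most one.

    With ``labels`` (patient id → class) the assignment is stratified:
    each class is dealt round-robin so every fold sees both classes
    whenever the counts allow it.
    """
    if len(train_ids) < fold_count:
        raise ValueError(
            f"training set of {len(train_ids)} too small for "
            f"{fold_count} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(train_ids))
    if labels is not None:
        by_class = [[p for p in order if labels[p] == c] for c in (1, 0)]
        folds = [[] for _ in range(fold_count)]
        i = 0
        for group in by_class:
            for pid in group:
                folds[i % fold_count].append(pid)
                i += 1
        return folds
    base, extra = divmod(len(order), fold_count)
    folds, start = [], 0
    for i in range(fold_count):
        size = base + (1 if i < extra else 0)
        folds.append(order[start:start + size])
        start += size
    return folds


def cv_rounds(folds: list[list[str]]):
    """Yield (train_ids, val_ids) per CV round: 4 folds train, 1 validates."""
    for i in range(len(folds)):
        val = folds[i]
        train = [pid for j, f in enumerate(folds) if j != i for pid in f]
        yield train, val


# ------------------------------------------------------------- augmentation

@dataclass
class AugmentConfig:
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0)
    noise_sd: float = 0.02
    elastic_spacing: int = 8        # control-point spacing in voxels
    elastic_sd: float = 2.0         # displacement standard deviation, voxels
    flip_axis: int = 2              # left-right by default
    seed: int = 0

    def validate(self):
        lo, hi = self.rotation_range_deg
        if lo < -180 or hi > 180 or lo > hi:
            raise ValueError("rotation range must lie within [-180, 180]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Sample:
    """One training item: a preprocessed volume plus its provenance."""
    volume: np.ndarray
    label: int
    patient_id: str
    augmented: bool = False
    augment_kind: str = "original"


def flip_volume(v: np.ndarray, axis: int = 2) -> np.ndarray:
    return np.flip(v, axis=axis).copy()


def rotate_volume(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation about the first axis (slices are square)."""
    out = rotate(v, angle_deg, axes=(1, 2), reshape=False, order=1,
                 mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def noise_volume(v: np.ndarray, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    return np.clip(v + rng.normal(0.0, sd, v.shape), 0.0, 1.0)


def elastic_volume(v: np.ndarray, spacing: int, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement field from a coarse control-point grid."""
    coarse = tuple(max(s // spacing, 2) for s in v.shape)
    disp = [rng.normal(0.0, sd, coarse) for _ in range(3)]
    fields = [zoom(d, np.array(v.shape) / np.array(coarse), order=1)
              for d in disp]
    grid = np.meshgrid(*[np.arange(s, dtype=float) for s in v.shape],
                       indexing="ij")
    coords = [g + f[:v.shape[0], :v.shape[1], :v.shape[2]]
              for g, f in zip(grid, fields)]
    out = map_coordinates(v, coords, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def augment_fold(samples: list[Sample],
                 config: AugmentConfig | None = None) -> list[Sample]:
    """Originals plus one copy per augmentation type (flip, rotation,
    Gaussian noise, elastic deformation): n inputs → 5n outputs."""
    cfg = config or AugmentConfig()
    cfg.validate()
    out: list[Sample] = []
    for i, s in enumerate(samples):
        v = np.asarray(s.volume, dtype=np.float64)
        if v.min() < -1e-6 or v.max() > 1 + 1e-6:
            raise ValueError(
                f"sample {s.patient_id}: volume not in [0,1] "
                f"(range [{v.min():.4g}, {v.max():.4g}]); normalize first")
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, i]))
        out.append(s)
        kinds = [
            ("flip", flip_volume(v, cfg.flip_axis)),
            ("rotate", rotate_volume(
                v, float(rng.uniform(*cfg.rotation_range_deg)))),
            ("noise", noise_volume(v, cfg.noise_sd, rng)),
            ("elastic", elastic_volume(v, cfg.elastic_spacing,
                                       cfg.elastic_sd, rng)),
        ]
        for kind, vol in kinds:
            out.append(Sample(volume=vol, label=s.label,
                              patient_id=s.patient_id, augmented=True,
                              augment_kind=kind))
    return out


def balance_by_pruning(samples: list[Sample], seed: int = 0) -> list[Sample]:
    """Randomly prune the majority class until the class counts are equal.

    Augmented copies are removed before originals; within each tier removal
    is uniformly random and deterministic given the seed.
    """
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    if len(pos) == len(neg):
        return list(samples)
    major, minor = (pos, neg) if len(pos) > len(neg) else (neg, pos)
    excess = len(major) - len(minor)
    rng = np.random.default_rng(seed)
    aug_idx = [i for i, s in enumerate(major) if s.augmented]
    orig_idx = [i for i, s in enumerate(major) if not s.augmented]
    drop: set[int] = set()
    take_aug = min(excess, len(aug_idx))
    drop.update(rng.choice(aug_idx, size=take_aug, replace=False).tolist())
    if excess > take_aug:
        drop.update(rng.choice(orig_idx, size=excess - take_aug,
                               replace=False).tolist())
    # preserve input order while dropping exactly the chosen items
    major_drop_ids = {id(major[i]) for i in drop}
    return [s for s in samples if id(s) not in major_drop_ids]
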