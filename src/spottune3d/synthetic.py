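"""Synthetic multi-modality brain-phantom cohort generator.

Emulates the structure of a BraTS-style glioblastoma collection: per-patient
NIfTI volumes for up to 11 MR modalities (4 structural, 4 DTI derivatives,
3 DSC derivatives), a three-subregion tumor mask (enhancing rim, necrotic
core, edema), and a metadata table with a binary MGMT-methylation label,
gender and age band. Modality availability is strictly nested
(DSC ⊂ DTI ⊂ structural), mirroring how shared train/test splits across
modalities are defined downstream.

The phantom anatomy is deliberately simple: an ellipsoidal tumor with three
nested subregions at a random in-volume center on a smoothed-noise
background. The class signal is a single additive mean shift of
``effect_size`` applied to the enhancing-rim voxels of methylated patients,
so task difficulty is controlled by one knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

STRUCTURAL_MODALITIES = ("T1", "T1GD", "T2", "FLAIR")
DTI_MODALITIES = ("DTI_Trace", "DTI_AD", "DTI_RD", "DTI_FA")
DSC_MODALITIES = ("DSC_PH", "DSC_PSR", "DSC_rCBV")
ALL_MODALITIES = STRUCTURAL_MODALITIES + DTI_MODALITIES + DSC_MODALITIES

MODALITY_GROUPS = {
    "structural": STRUCTURAL_MODALITIES,
    "dti": DTI_MODALITIES,
    "dsc": DSC_MODALITIES,
}

# BraTS label dialect: 1 = necrotic core, 2 = edema, 4 = enhancing tumor
NECROTIC, EDEMA, ENHANCING = 1, 2, 4

AGE_BANDS = ("18-29", "30-49", "50-69", "70+")


class CohortConfigError(ValueError):
    """Raised when a cohort specification's counts are inconsistent."""


@dataclass
class PatientRecord:
    patient_id: str
    label: int                      # 1 = methylated (positive class)
    gender: str                     # "male" | "female"
    age_group: str
    modalities: tuple[str, ...]

    @property
    def has_dti(self) -> bool:
        return DTI_MODALITIES[0] in self.modalities

    @property
    def has_dsc(self) -> bool:
        return DSC_MODALITIES[0] in self.modalities


@dataclass
class CohortSpec:
    """Counts and signal parameters defining a phantom cohort.

    Defaults reproduce the study cohort: 240 patients with structural MRI,
    a 208-patient DTI subset and a 189-patient DSC subset; 102 methylated /
    138 unmethylated overall, 81/108 within DSC.  The DTI subset uses
    91 methylated / 117 unmethylated so its class counts sum to 208.
    ``class_counts`` entries are (methylated, unmethylated).
    """

    n_total: int = 240
    n_dti: int = 208
    n_dsc: int = 189
    class_counts: dict = field(default_factory=lambda: {
        "structural": (102, 138), "dti": (91, 117), "dsc": (81, 108)})
    gender_counts: dict = field(default_factory=lambda: {
        "male": (62, 88), "female": (40, 50)})
    age_group_counts: dict = field(default_factory=lambda: {
        "18-29": (1, 5), "30-49": (6, 17), "50-69": (64, 82), "70+": (31, 34)})
    volume_shape: tuple[int, int, int] = (155, 240, 240)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    effect_size: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_dsc <= self.n_dti <= self.n_total):
            raise CohortConfigError(
                f"nesting violated: need n_dsc <= n_dti <= n_total, got "
                f"n_dsc={self.n_dsc}, n_dti={self.n_dti}, n_total={self.n_total}")
        subset_totals = {"structural": self.n_total, "dti": self.n_dti,
                         "dsc": self.n_dsc}
        for name, (pos, neg) in self.class_counts.items():
            if pos + neg != subset_totals[name]:
                raise CohortConfigError(
                    f"class_counts[{name!r}]: {pos}+{neg} != {subset_totals[name]}")
        pos_tot, neg_tot = self.class_counts["structural"]
        # nested class counts must be monotone
        for small, big in (("dsc", "dti"), ("dti", "structural")):
            for i in range(2):
                if self.class_counts[small][i] > self.class_counts[big][i]:
                    raise CohortConfigError(
                        f"class_counts[{small!r}] exceeds class_counts[{big!r}]")
        g_pos = sum(v[0] for v in self.gender_counts.values())
        g_neg = sum(v[1] for v in self.gender_counts.values())
        if (g_pos, g_neg) != (pos_tot, neg_tot):
            raise CohortConfigError(
                f"gender_counts sum to ({g_pos},{g_neg}), expected "
                f"({pos_tot},{neg_tot})")
        a_pos = sum(v[0] for v in self.age_group_counts.values())
        a_neg = sum(v[1] for v in self.age_group_counts.values())
        if (a_pos, a_neg) != (pos_tot, neg_tot):
            raise CohortConfigError(
                f"age_group_counts sum to ({a_pos},{a_neg}), expected "
                f"({pos_tot},{neg_tot})")
        if min(self.volume_shape) < 8:
            raise CohortConfigError("volume_shape axes must each be >= 8")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be >= 0")

    @classmethod
    def small(cls, n_total: int = 40, n_dti: int | None = None,
              n_dsc: int | None = None, shape: tuple = (32, 32, 32),
              effect_size: float = 0.5, noise_sd: float = 0.1,
              seed: int = 0) -> "CohortSpec":
        """A reduced, internally consistent spec for desk-scale work.

        Class/gender/age counts are scaled proportionally from the study
        cohort and rounded so every marginal still sums exactly.
        """
        n_dti = n_total if n_dti is None else n_dti
        n_dsc = n_dti if n_dsc is None else n_dsc
        if not (n_dsc <= n_dti <= n_total):
            raise CohortConfigError("need n_dsc <= n_dti <= n_total")

        def split_pos(n):
            return int(round(n * 102 / 240))

        cc = {"structural": (split_pos(n_total), n_total - split_pos(n_total)),
              "dti": (split_pos(n_dti), n_dti - split_pos(n_dti)),
              "dsc": (split_pos(n_dsc), n_dsc - split_pos(n_dsc))}
        # enforce monotone nesting after rounding
        for small_, big_ in (("dsc", "dti"), ("dti", "structural")):
            p = min(cc[small_][0], cc[big_][0])
            tot = sum(cc[small_])
            cc[small_] = (p, tot - p)
        pos, neg = cc["structural"]
        m_pos = pos * 62 // 102
        m_neg = neg * 88 // 138
        gc = {"male": (m_pos, m_neg), "female": (pos - m_pos, neg - m_neg)}
        # put everything in the dominant age band except a token split
        ac = {"18-29": (0, 0), "30-49": (0, 0),
              "50-69": (pos - pos // 3, neg - neg // 3),
              "70+": (pos // 3, neg // 3)}
        return cls(n_total=n_total, n_dti=n_dti, n_dsc=n_dsc, class_counts=cc,
                   gender_counts=gc, age_group_counts=ac, volume_shape=shape,
                   effect_size=effect_size, noise_sd=noise_sd, seed=seed)


@dataclass
class Cohort:
    """Generated cohort: records plus deterministic on-demand volumes."""

    spec: CohortSpec
    records: list[PatientRecord]

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def mask(self, patient_id: str) -> np.ndarray:
        """Three-subregion tumor mask (BraTS codes 1/2/4) for one patient."""
        return _make_mask(self.spec, self._patient_index(patient_id))

    def volume(self, patient_id: str, modality: str) -> np.ndarray:
        """One modality's voxel grid; bit-identical across calls."""
        rec = self.record(patient_id)
        if modality not in rec.modalities:
            raise KeyError(f"{patient_id} has no {modality} volume")
        idx = self._patient_index(patient_id)
        return _make_volume(self.spec, idx, ALL_MODALITIES.index(modality),
                            rec.label)

    def _patient_index(self, patient_id: str) -> int:
        for i, r in enumerate(self.records):
            if r.patient_id == patient_id:
                return i
        raise KeyError(patient_id)


# --------------------------------------------------------------------- guts

def _tumor_geometry(spec: CohortSpec, idx: int):
    """Deterministic tumor center and subregion half-axes for patient idx."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx, 7]))
    shape = np.asarray(spec.volume_shape, dtype=float)
    r_edema = 0.28 * shape / 2.0
    r_rim = 0.18 * shape / 2.0
    r_core = 0.09 * shape / 2.0
    lo = r_edema + 1
    hi = shape - r_edema - 1
    center = lo + rng.random(3) * (hi - lo)
    return center, r_edema, r_rim, r_core


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _make_mask(spec: CohortSpec, idx: int) -> np.ndarray:
    center, r_edema, r_rim, r_core = _tumor_geometry(spec, idx)
    shape = spec.volume_shape
    edema = _ellipsoid(shape, center, r_edema)
    rim = _ellipsoid(shape, center, r_rim)
    core = _ellipsoid(shape, center, r_core)
    mask = np.zeros(shape, dtype=np.int16)
    mask[edema] = EDEMA
    mask[rim] = ENHANCING
    mask[core] = NECROTIC
    return mask


def _make_volume(spec: CohortSpec, idx: int, modality_idx: int,
                 label: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, idx, modality_idx]))
    shape = spec.volume_shape
    noise = rng.standard_normal(shape)
    background = gaussian_filter(noise, sigma=1.5)
    sd = background.std()
    if sd > 0 and spec.noise_sd > 0:
        background *= spec.noise_sd / sd
    elif spec.noise_sd == 0:
        background[...] = 0.0
    vol = 1.0 + background
    mask = _make_mask(spec, idx)
    vol[mask == EDEMA] += 0.3
    vol[mask == ENHANCING] += 0.6
    vol[mask == NECROTIC] += 0.15
    if label == 1:
        vol[mask == ENHANCING] += spec.effect_size
    return vol


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Build the patient table with exactly the specified marginal counts.

    Deterministic given ``spec.seed``: the same spec always yields the same
    records and (through :class:`Cohort`) bit-identical volumes.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))

    n_extra_dti = spec.n_dti - spec.n_dsc
    n_extra_struct = spec.n_total - spec.n_dti
    pos_dsc, neg_dsc = spec.class_counts["dsc"]
    pos_dti, neg_dti = spec.class_counts["dti"]
    pos_all, neg_all = spec.class_counts["structural"]

    labels = (
        [1] * pos_dsc + [0] * neg_dsc +
        [1] * (pos_dti - pos_dsc) + [0] * (neg_dti - neg_dsc) +
        [1] * (pos_all - pos_dti) + [0] * (neg_all - neg_dti))
    tiers = (["dsc"] * spec.n_dsc + ["dti"] * n_extra_dti +
             ["structural"] * n_extra_struct)

    # assign gender and age bands independently within each class so that
    # every stated class-conditional marginal is met exactly
    def assign(counts: dict) -> list[str]:
        out = [None] * spec.n_total
        for cls in (1, 0):
            idxs = [i for i, b in enumerate(labels) if b == cls]
            perm = rng.permutation(len(idxs))
            pool = []
            for name, pair in counts.items():
                pool += [name] * pair[0 if cls == 1 else 1]
            for j, p in enumerate(perm):
                out[idxs[p]] = pool[j]
        return out

    genders = assign(spec.gender_counts)
    ages = assign(spec.age_group_counts)

    records = []
    for i in range(spec.n_total):
        tier = tiers[i]
        mods = STRUCTURAL_MODALITIES
        if tier in ("dsc", "dti"):
            mods = mods + DTI_MODALITIES
        if tier == "dsc":
            mods = mods + DSC_MODALITIES
        records.append(PatientRecord(
            patient_id=f"SYN-{i:04d}", label=labels[i], gender=genders[i],
            age_group=ages[i], modalities=tuple(mods)))
    return Cohort(spec=spec, records=records)


def summarize_cohort(records: list[PatientRecord]) -> pd.DataFrame:
    """Demographic summary table (counts and percentages).

    Characteristic percentages are relative to the cohort total; the
    methylated/unmethylated percentages are relative to the characteristic's
    own count, each to one decimal place.  The per-gender
    methylated:unmethylated ratio is reported to one decimal place and is
    NaN when a gender has no unmethylated patients.
    """
    if not records:
        raise ValueError("summarize_cohort: empty record list")
    n = len(records)
    rows = []
    groups = [("gender", ["male", "female"], lambda r: r.gender),
              ("age", list(AGE_BANDS), lambda r: r.age_group)]
    for characteristic, levels, key in groups:
        for level in levels:
            sub = [r for r in records if key(r) == level]
            cnt = len(sub)
            pos = sum(r.label for r in sub)
            neg = cnt - pos
            ratio = round(pos / neg, 1) if neg > 0 else float("nan")
            rows.append({
                "characteristic": characteristic,
                "level": level,
                "count": cnt,
                "percent": round(100.0 * cnt / n, 1),
                "methylated": pos,
                "methylated_percent":
                    round(100.0 * pos / cnt, 1) if cnt else float("nan"),
                "unmethylated": neg,
                "unmethylated_percent":
                    round(100.0 * neg / cnt, 1) if cnt else float("nan"),
                "methylated_unmethylated_ratio": ratio,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- on disk

def write_cohort(cohort: Cohort, out_dir: str | Path,
                 modalities: tuple[str, ...] | None = None) -> Path:
    """Write BraTS-style per-patient directories of NIfTI volumes and masks
    plus a ``metadata.csv`` table. Returns the output directory."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(cohort.spec.spacing_mm) + [1.0])
    meta_rows = []
    for rec in cohort.records:
        pdir = out / rec.patient_id
        pdir.mkdir(exist_ok=True)
        mods = rec.modalities if modalities is None else tuple(
            m for m in modalities if m in rec.modalities)
        for m in mods:
            img = nib.Nifti1Image(
                cohort.volume(rec.patient_id, m).astype(np.float32), affine)
            nib.save(img, pdir / f"{rec.patient_id}_{m}.nii.gz")
        seg = nib.Nifti1Image(
            cohort.mask(rec.patient_id).astype(np.int16), affine)
        nib.save(seg, pdir / f"{rec.patient_id}_segm.nii.gz")
        row = {"patient_id": rec.patient_id, "label": rec.label,
               "gender": rec.gender, "age_group": rec.age_group}
        for m in ALL_MODALITIES:
            row[m] = int(m in rec.modalities)
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    return out


def read_metadata(path: str | Path) -> list[PatientRecord]:
    """Load a metadata.csv written by :func:`write_cohort`."""
    df = pd.read_csv(Path(path))
    records = []
    for _, row in df.iterrows():
        mods = tuple(m for m in ALL_MODALITIES if int(row[m]) == 1)
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]), label=int(row["label"]),
            gender=str(row["gender"]), age_group=str(row["age_group"]),
            modalities=mods))
    return records
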