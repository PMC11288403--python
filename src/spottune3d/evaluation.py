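"""Metrics, stochastic-policy ensemble evaluation, and model comparison.

AUC and average precision come from scikit-learn (rank/Mann–Whitney AUC
with midrank tie handling; AP as the precision-weighted recall sum);
sensitivity and specificity are taken at a probability threshold of 0.5
with methylated as the positive class. SpotTune models are evaluated by
drawing many hard routing policies per patient (100 by default, seed 42)
and averaging the resulting probabilities; CV folds and modality groups
are combined by the arithmetic mean of output probabilities. Network
categories are compared with a tie-corrected Friedman test followed, when
significant, by a Nemenyi post-hoc test on mean ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, studentized_range
from sklearn.metrics import average_precision_score, roc_auc_score

from .training import selection_metric

ENSEMBLE_GROUPS = {
    "DSC": ("DSC_PH", "DSC_PSR", "DSC_rCBV"),
    "DTI": ("DTI_Trace", "DTI_AD", "DTI_RD", "DTI_FA"),
    "Struct": ("T2", "FLAIR", "T1", "T1GD"),
}
ENSEMBLE_GROUPS.update({
    "DSC+DTI": ENSEMBLE_GROUPS["DSC"] + ENSEMBLE_GROUPS["DTI"],
    "DSC+Struct": ENSEMBLE_GROUPS["DSC"] + ENSEMBLE_GROUPS["Struct"],
    "DTI+Struct": ENSEMBLE_GROUPS["DTI"] + ENSEMBLE_GROUPS["Struct"],
    "DSC+DTI+Struct": (ENSEMBLE_GROUPS["DSC"] + ENSEMBLE_GROUPS["DTI"]
                       + ENSEMBLE_GROUPS["Struct"]),
})


@dataclass
class EvalResult:
    probabilities: np.ndarray
    auc: float
    ap: float
    sen: float
    spe: float
    m: float
    undefined: bool = False     # single-class labels: AUC/AP undefined


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> EvalResult:
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    y = np.asarray(labels).reshape(-1).astype(int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    if len(set(y)) < 2:
        return EvalResult(p, float("nan"), float("nan"), sen, spe,
                          float("nan"), undefined=True)
    auc = float(roc_auc_score(y, p))
    ap = float(average_precision_score(y, p))
    return EvalResult(p, auc, ap, sen, spe, selection_metric(sen, spe))


def stochastic_eval(predict_fn, labels: np.ndarray, n_samples: int = 100,
                    seed: int = 42, stochastic: bool = True) -> EvalResult:
    """Mean-probability evaluation over repeated stochastic policies.

    ``predict_fn(sample_index, rng_seed)`` must return the per-patient
    probability vector for one fresh hard-policy draw. For deterministic
    (non-SpotTune) models one call suffices and the result equals a single
    pass.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not stochastic:
        return compute_metrics(predict_fn(0, seed), labels)
    acc = None
    for s in range(n_samples):
        p = np.asarray(predict_fn(s, seed), dtype=float)
        acc = p if acc is None else acc + p
    return compute_metrics(acc / n_samples, labels)


def ensemble_mean(prob_vectors: list[np.ndarray],
                  patient_ids: list[list] | None = None) -> np.ndarray:
    """Arithmetic mean of aligned per-patient probability vectors.

    Applied first across the CV folds of one modality, then across the
    modalities of a group. Misaligned patient sets raise with the offending
    ids listed.
    """
    if not prob_vectors:
        raise ValueError("no probability vectors to ensemble")
    if patient_ids is not None:
        ref = list(patient_ids[0])
        for ids in patient_ids[1:]:
            if list(ids) != ref:
                extra = sorted(set(map(str, ids)) ^ set(map(str, ref)))
                raise ValueError(f"misaligned patient sets: {extra}")
    arrs = [np.asarray(v, dtype=float).reshape(-1) for v in prob_vectors]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("probability vectors differ in length")
    return np.mean(arrs, axis=0)


def roc_pr_points(probabilities: np.ndarray,
                  labels: np.ndarray) -> "pd.DataFrame":
    """ROC and precision-recall curve points in long form (curve, x, y),
    ready for CSV export."""
    import pandas as pd
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = np.asarray(labels).reshape(-1).astype(int)
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    fpr, tpr, _ = roc_curve(y, p)
    prec, rec, _ = precision_recall_curve(y, p)
    rows = [{"curve": "roc", "x": float(a), "y": float(b)}
            for a, b in zip(fpr, tpr)]
    rows += [{"curve": "pr", "x": float(r), "y": float(q)}
             for r, q in zip(rec, prec)]
    return pd.DataFrame(rows)


# ------------------------------------------------------- statistical tests

def friedman_test(scores: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square on an (n subjects × k models)
    score matrix. Returns (statistic, p value); identical columns give
    statistic 0 and p = 1."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("need an (n, k>=3) paired score matrix")
    n, k = x.shape
    from scipy.stats import rankdata
    ranks = np.apply_along_axis(rankdata, 1, x)     # midranks within subject
    rbar = ranks.mean(axis=0)
    ss = n * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction: average squared deviation of within-subject ranks
    denom = np.sum((ranks - (k + 1) / 2.0) ** 2) / (n * (k - 1))
    if denom == 0:
        return 0.0, 1.0
    stat = ss / denom
    return float(stat), float(chi2.sf(stat, k - 1))


def nemenyi_test(scores: np.ndarray) -> np.ndarray:
    """Pairwise Nemenyi p-values (k × k) from the studentized-range
    distribution on mean within-subject ranks."""
    x = np.asarray(scores, dtype=float)
    n, k = x.shape
    from scipy.stats import rankdata
    ranks = np.apply_along_axis(rankdata, 1, x)
    rbar = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(rbar[i] - rbar[j]) / se * math.sqrt(2.0)
            p = float(studentized_range.sf(q, k, np.inf))
            pvals[i, j] = pvals[j, i] = p
    return pvals


def compare_networks(scores: dict[str, np.ndarray],
                     alpha: float = 0.05) -> dict:
    """Friedman test across k ≥ 3 paired per-patient score vectors, with
    Nemenyi pairwise p-values reported when the Friedman test is
    significant at ``alpha``.

    The paired score for each patient is, by convention, the probability
    the model assigns to that patient's true class.
    """
    names = list(scores)
    if len(names) < 3:
        raise ValueError("need at least 3 network categories")
    arrs = [np.asarray(scores[n], dtype=float).reshape(-1) for n in names]
    sizes = {a.size for a in arrs}
    if len(sizes) != 1:
        raise ValueError("unpaired inputs: score vectors differ in length")
    mat = np.column_stack(arrs)
    stat, p = friedman_test(mat)
    out = {"friedman_statistic": stat, "friedman_p": p, "models": names,
           "nemenyi_p": None}
    if p < alpha:
        pv = nemenyi_test(mat)
        out["nemenyi_p"] = {
            (names[i], names[j]): float(pv[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))}
    return out


def true_class_probability(probabilities: np.ndarray,
                           labels: np.ndarray) -> np.ndarray:
    """Per-patient probability assigned to the patient's true class."""
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    y = np.asarray(labels).reshape(-1)
    return np.where(y == 1, p, 1.0 - p)
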