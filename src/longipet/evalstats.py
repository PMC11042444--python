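"""Lesion-detection scoring, Deauville agreement, bootstrap machinery.

Detection follows the overlap protocol: a predicted component is a true
positive if it shares at least one voxel with any non-equivocal
reference lesion; a reference lesion no prediction touches is a false
negative; predictions touching only equivocal reference lesions are
excluded from the counts entirely.  The stricter variant additionally
requires the predicted component to reproduce the reference lesion's
SUVmax (both are read off the same PET grid, so the default tolerance
is exact equality); a pair failing that check contributes one false
positive and one false negative.

Confidence intervals come from a nonparametric patient-level bootstrap
(default 10,000 trials, 2.5/97.5 percentiles); paired superiority is
declared at the 0.05 level when one method's statistic strictly exceeds
the other's in at least 95% of joint resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .inference_post import LesionComponent

__all__ = [
    "MatchResult",
    "BootstrapResult",
    "match_overlap",
    "match_suvmax",
    "segmentation_scores",
    "prf",
    "ds_agreement",
    "bootstrap_ci",
    "paired_superiority",
    "spearman_rho",
    "pooled_detection_f1",
]


@dataclass
class MatchResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    pairs: list = field(default_factory=list)          # (pred label, true label)
    excluded_equivocal: int = 0
    matched_true: int = 0                              # distinct matched truths

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn,
            pairs=self.pairs + other.pairs,
            excluded_equivocal=self.excluded_equivocal + other.excluded_equivocal,
            matched_true=self.matched_true + other.matched_true)


def _voxel_sets(components):
    return [set(map(tuple, c.voxels)) for c in components]


def match_overlap(pred: list[LesionComponent],
                  true: list[LesionComponent]) -> MatchResult:
    """Overlap criterion with equivocal exclusion.

    Prediction-side classification: TP if a prediction overlaps any
    non-equivocal truth; excluded if it overlaps equivocal truths only;
    FP otherwise.  Truth-side: a non-equivocal truth with no overlapping
    prediction is an FN; equivocal truths are never counted.
    """
    res = MatchResult()
    true_sets = _voxel_sets(true)
    matched_true: set[int] = set()
    for p, pset in zip(pred, _voxel_sets(pred)):
        hits = [t for t, tset in zip(true, true_sets) if pset & tset]
        neq_hits = [t for t in hits if not t.equivocal]
        if neq_hits:
            res.tp += 1
            for t in neq_hits:
                res.pairs.append((p.label, t.label))
                matched_true.add(t.label)
        elif hits:
            res.excluded_equivocal += 1
        else:
            res.fp += 1
    res.fn = sum(1 for t in true if not t.equivocal and t.label not in matched_true)
    res.matched_true = len(matched_true)
    return res


def match_suvmax(pred: list[LesionComponent], true: list[LesionComponent],
                 tolerance: float = 0.0) -> MatchResult:
    """Stricter criterion: an overlap match survives only if the
    prediction's SUVmax equals the truth's within ``tolerance``.

    A demoted pair yields one FP (the prediction) and one FN (the truth).
    """
    base = match_overlap(pred, true)
    res = MatchResult(excluded_equivocal=base.excluded_equivocal,
                      fp=base.fp)
    pred_by_label = {p.label: p for p in pred}
    true_by_label = {t.label: t for t in true}
    ok_preds: set[int] = set()
    bad_preds: set[int] = set()
    matched_true: set[int] = set()
    for pl, tl in base.pairs:
        if abs(pred_by_label[pl].suvmax - true_by_label[tl].suvmax) <= tolerance:
            ok_preds.add(pl)
            matched_true.add(tl)
            res.pairs.append((pl, tl))
        else:
            bad_preds.add(pl)
    bad_preds -= ok_preds
    res.tp = len(ok_preds)
    res.fp += len(bad_preds)
    res.fn = sum(1 for t in true if not t.equivocal and t.label not in matched_true)
    res.matched_true = len(matched_true)
    return res


def segmentation_scores(pred_mask: np.ndarray, true_mask: np.ndarray,
                        spacing) -> dict:
    """Dice, false-positive volume and false-negative volume (mL).

    Two empty masks score Dice 1 by convention.
    """
    if pred_mask.shape != true_mask.shape:
        raise ValueError("mask grids differ")
    p = pred_mask > 0
    t = true_mask > 0
    voxel_ml = float(np.prod(spacing)) / 1000.0
    inter = int((p & t).sum())
    psum, tsum = int(p.sum()), int(t.sum())
    dice = 1.0 if psum + tsum == 0 else 2.0 * inter / (psum + tsum)
    return {
        "dice": float(dice),
        "fpv_ml": float((psum - inter) * voxel_ml),
        "fnv_ml": float((tsum - inter) * voxel_ml),
    }


def prf(tp: int, fp: int, fn: int) -> dict:
    """Precision/recall/F1 with flagged zeros for 0/0 cases."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    degenerate = {"precision": tp + fp == 0, "recall": tp + fn == 0}
    precision = 0.0 if degenerate["precision"] else tp / (tp + fp)
    recall = 0.0 if degenerate["recall"] else tp / (tp + fn)
    if precision + recall == 0:
        f1, deg_f1 = 0.0, True
    else:
        f1, deg_f1 = 2 * precision * recall / (precision + recall), False
    return {"precision": precision, "recall": recall, "f1": f1,
            "degenerate": {**degenerate, "f1": deg_f1}}


def pooled_detection_f1(results: list[MatchResult]) -> dict:
    """Micro-averaged cohort detection scores (counts pooled, then PRF)."""
    total = MatchResult()
    for r in results:
        total = total + r
    return prf(total.tp, total.fp, total.fn)


def ds_agreement(pred_ds: list, true_ds: list, threshold: int = 3) -> dict:
    """Binary response agreement at DS >= threshold: F1 (positive =
    inadequate response) and Cohen's kappa from the 2x2 table."""
    from .quant import ds_band_positive

    if len(pred_ds) != len(true_ds):
        raise ValueError("prediction and reference lists differ in length")
    p = np.array([ds_band_positive(str(d), threshold) for d in pred_ds])
    t = np.array([ds_band_positive(str(d), threshold) for d in true_ds])
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    n = len(p)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1 - pe)
    return {**prf(tp, fp, fn), "kappa": float(kappa), "table": (tp, fp, fn, tn)}


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_trials: int
    seed: int
    redrawn: int = 0
    superiority_fraction: float | None = None

    @property
    def significant(self) -> bool:
        """0.05-level paired superiority: wins in >= 95% of trials."""
        if self.superiority_fraction is None:
            raise ValueError("not a paired comparison")
        return self.superiority_fraction >= 0.95


def bootstrap_ci(per_patient_values, statistic=None, n_trials: int = 10000,
                 seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap over patients.

    ``per_patient_values`` is a sequence of per-patient items (numbers or
    richer objects); ``statistic`` maps a list of items to a scalar
    (default: mean of numeric values).  Patients are resampled with
    replacement; a resample on which the statistic is undefined (raises
    or returns NaN) is redrawn and counted.
    """
    items = list(per_patient_values)
    if len(items) < 2:
        raise ValueError("need >= 2 patients")
    if statistic is None:
        statistic = lambda vals: float(np.mean(vals))
    rng = np.random.default_rng(seed)
    est = float(statistic(items))
    draws = np.empty(n_trials)
    redrawn = 0
    i = 0
    while i < n_trials:
        idx = rng.integers(0, len(items), size=len(items))
        try:
            val = float(statistic([items[j] for j in idx]))
        except (ZeroDivisionError, ValueError, FloatingPointError):
            val = np.nan
        if not np.isfinite(val):
            redrawn += 1
            if redrawn > 100 * n_trials:
                raise RuntimeError("statistic undefined on nearly all resamples")
            continue
        draws[i] = val
        i += 1
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapResult(est, float(lo), float(hi), n_trials, seed, redrawn)


def paired_superiority(per_patient_a, per_patient_b, statistic=None,
                       n_trials: int = 10000, seed: int = 0) -> BootstrapResult:
    """Joint patient resampling; superiority_fraction = P(stat_a > stat_b).

    Ties never count as wins, so identical arms give fraction ~0.
    """
    a, b = list(per_patient_a), list(per_patient_b)
    if len(a) != len(b):
        raise ValueError("arms must cover the same patients")
    if statistic is None:
        statistic = lambda vals: float(np.mean(vals))
    rng = np.random.default_rng(seed)
    wins = 0
    valid = 0
    redrawn = 0
    while valid < n_trials:
        idx = rng.integers(0, len(a), size=len(a))
        try:
            sa = float(statistic([a[j] for j in idx]))
            sb = float(statistic([b[j] for j in idx]))
        except (ZeroDivisionError, ValueError, FloatingPointError):
            sa = np.nan
            sb = np.nan
        if not (np.isfinite(sa) and np.isfinite(sb)):
            redrawn += 1
            if redrawn > 100 * n_trials:
                raise RuntimeError("statistic undefined on nearly all resamples")
            continue
        wins += sa > sb
        valid += 1
    frac = wins / n_trials
    est_a = float(statistic(a))
    est_b = float(statistic(b))
    return BootstrapResult(est_a - est_b, np.nan, np.nan, n_trials, seed, redrawn,
                           superiority_fraction=frac)


def spearman_rho(x, y, n_trials: int = 0, seed: int = 0):
    """Spearman rank correlation (average ranks over ties); optional
    patient-level bootstrap CI when ``n_trials`` > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": np.nan, "degenerate": True, "ci": None}
    rho = float(sstats.spearmanr(x, y).statistic)
    out = {"rho": rho, "degenerate": False, "ci": None}
    if n_trials:
        pairs = list(zip(x, y))

        def stat(items):
            xs = np.array([p[0] for p in items])
            ys = np.array([p[1] for p in items])
            if np.all(xs == xs[0]) or np.all(ys == ys[0]):
                return np.nan
            return float(sstats.spearmanr(xs, ys).statistic)

        bs = bootstrap_ci(pairs, stat, n_trials=n_trials, seed=seed)
        out["ci"] = (bs.ci_low, bs.ci_high)
    return out
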