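"""Joint two-branch optimization: compound loss, patch sampling, folds.

The network is trained on paired baseline/interim patches cropped at the
same location of the co-registered grids, with a foreground-biased
sampler (lesions occupy a tiny fraction of a torso volume).  The loss is
the sum over branches of cross-entropy plus soft Dice.  Voxels belonging
to equivocal reference lesions can be excluded from the loss entirely
(the default), treated as foreground, or treated as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.modules import DTYPE
from .model import LASNet, LASNetConfig, prepare_input

__all__ = [
    "TrainConfig",
    "EQUIVOCAL_LABEL",
    "compound_loss",
    "build_label_volume",
    "sample_patches",
    "make_folds",
    "train",
]

EQUIVOCAL_LABEL = 2
DICE_EPS = 1e-5


@dataclass
class TrainConfig:
    steps: int = 300
    batch_size: int = 2
    patch_size: tuple[int, int, int] = (24, 24, 24)
    patches_per_volume: int = 4
    fg_ratio: float = 2.0 / 3.0   # fraction of patches centered on lesions (2:1)
    # among lesion-centered patches, fraction centered specifically on
    # interim-positive voxels; off by default (residual-heavy sampling
    # starves the model of organ/background negatives)
    interim_fg_ratio: float = 0.0
    lr: float = 3e-3
    weight_decay: float = 1e-5
    warmup_steps: int = 10
    lr_floor: float = 0.15    # late-phase lr fraction of the cosine schedule
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    # CE class weight on lesion voxels: lesions occupy a tiny fraction of
    # any patch (residual disease especially), and unweighted CE lets
    # "predict nothing" persist as a stable optimum
    fg_class_weight: float = 4.0
    branch_weights: tuple[float, float] = (1.0, 1.0)
    equivocal_policy: str = "exclude_from_loss"
    seed: int = 0

    def validate(self) -> None:
        if self.ce_weight < 0 or self.dice_weight < 0 or min(self.branch_weights) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.equivocal_policy not in (
                "exclude_from_loss", "treat_as_foreground", "treat_as_background"):
            raise ValueError(f"unknown equivocal_policy {self.equivocal_policy!r}")


# ----------------------------------------------------------------------
# loss
# ----------------------------------------------------------------------

def _resolve_labels(labels: np.ndarray, policy: str):
    """Map a {0,1,EQUIVOCAL} label volume to (targets, weights)."""
    bad = set(np.unique(labels)) - {0, 1, EQUIVOCAL_LABEL}
    if bad:
        raise ValueError(f"labels contain unexpected values {sorted(bad)}")
    eq = labels == EQUIVOCAL_LABEL
    target = (labels == 1).astype(np.int64)
    weight = np.ones(labels.shape, dtype=DTYPE)
    if policy == "exclude_from_loss":
        weight[eq] = 0.0
    elif policy == "treat_as_foreground":
        target[eq] = 1
    # treat_as_background: target stays 0, weight stays 1
    return target, weight


def _branch_loss(logits: Tensor, labels: np.ndarray, cfg: TrainConfig) -> Tensor:
    """Weighted CE + soft Dice for one branch; logits (N,2,D,H,W)."""
    target, weight = _resolve_labels(labels, cfg.equivocal_policy)
    ce_arr = weight * np.where(target == 1, cfg.fg_class_weight, 1.0) \
        .astype(weight.dtype)
    w_ce = Tensor(ce_arr)
    wsum = max(float(ce_arr.sum()), 1.0)
    w = Tensor(weight)  # pure inclusion mask for the Dice term

    logp = nn.log_softmax(logits, axis=1)
    n, _, d, h, wd = logits.shape
    n_ix = np.arange(n)[:, None, None, None]
    d_ix = np.arange(d)[None, :, None, None]
    h_ix = np.arange(h)[None, None, :, None]
    w_ix = np.arange(wd)[None, None, None, :]
    picked = logp[(n_ix, target, d_ix, h_ix, w_ix)]
    ce = -(picked * w_ce).sum() * (1.0 / wsum)

    p_fg = nn.softmax(logits, axis=1)[:, 1]
    t_fg = Tensor((target == 1).astype(DTYPE))
    inter = (p_fg * t_fg * w).sum()
    denom = (p_fg * w).sum() + (t_fg * w).sum()
    dice = 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)
    return cfg.ce_weight * ce + cfg.dice_weight * dice


def compound_loss(logits1: Tensor | None, logits2: Tensor,
                  labels1: np.ndarray | None, labels2: np.ndarray,
                  cfg: TrainConfig) -> Tensor:
    """Sum over branches of w_b * (ce_weight*CE + dice_weight*SoftDice)."""
    cfg.validate()
    w1, w2 = cfg.branch_weights
    loss = w2 * _branch_loss(logits2, labels2, cfg)
    if logits1 is not None and labels1 is not None and w1 > 0:
        loss = loss + w1 * _branch_loss(logits1, labels1, cfg)
    return loss


# ----------------------------------------------------------------------
# data plumbing
# ----------------------------------------------------------------------

def build_label_volume(mask: np.ndarray, lesions) -> np.ndarray:
    """Collapse a labelled lesion mask to {0,1,EQUIVOCAL_LABEL}."""
    out = (mask > 0).astype(np.int16)
    for l in lesions:
        if l.equivocal:
            out[mask == l.label] = EQUIVOCAL_LABEL
    return out


@dataclass
class _PreparedStudy:
    x1: np.ndarray
    x2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    fg_voxels: np.ndarray   # (K,3) lesion voxels, union of both time points
    fg2_voxels: np.ndarray  # (K,3) interim lesion voxels only


def prepare_study(study) -> _PreparedStudy:
    x1 = prepare_input(study.pet1, study.ct1)
    x2 = prepare_input(study.pet2, study.ct2)
    y1 = build_label_volume(study.mask1, study.lesions1)
    y2 = build_label_volume(study.mask2, study.lesions2)
    fg = np.argwhere((y1 == 1) | (y2 == 1))
    fg2 = np.argwhere(y2 == 1)
    return _PreparedStudy(x1, x2, y1, y2, fg, fg2)


def _crop(arr: np.ndarray, center, size) -> np.ndarray:
    """Crop around a center with zero padding at the borders."""
    spatial = arr.shape[-3:]
    lo = [int(c) - s // 2 for c, s in zip(center, size)]
    pads, sls = [], []
    for ax in range(3):
        a, b = lo[ax], lo[ax] + size[ax]
        pads.append((max(-a, 0), max(b - spatial[ax], 0)))
        sls.append(slice(max(a, 0), min(b, spatial[ax])))
    out = arr[(..., *sls)]
    if any(p != (0, 0) for p in pads):
        pw = ((0, 0),) * (arr.ndim - 3) + tuple(pads)
        out = np.pad(out, pw)
    return out


def sample_patches(study, cfg: TrainConfig, rng: np.random.Generator,
                   prepared: _PreparedStudy | None = None):
    """Draw co-registered patch pairs with a foreground:background ratio.

    Foreground-centered patches pick a random lesion voxel (union of
    both time points' lesions) as center; background patches a uniform
    voxel.  A study with no lesions yields background patches only.
    """
    ps = prepared if prepared is not None else prepare_study(study)
    spatial = ps.x1.shape[-3:]
    out = []
    for _ in range(cfg.patches_per_volume):
        if len(ps.fg_voxels) and rng.uniform() < cfg.fg_ratio:
            pool = ps.fg_voxels
            if len(ps.fg2_voxels) and rng.uniform() < cfg.interim_fg_ratio:
                pool = ps.fg2_voxels
            center = pool[rng.integers(len(pool))]
        else:
            center = [rng.integers(s) for s in spatial]
        out.append(tuple(
            _crop(a, center, cfg.patch_size) for a in (ps.x1, ps.x2, ps.y1, ps.y2)))
    return out


def make_folds(patient_ids, k: int = 5, seed: int = 0) -> dict:
    """Deterministic patient-level partition into k near-equal folds."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} patients into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return folds


# ----------------------------------------------------------------------
# optimization loop
# ----------------------------------------------------------------------

def train(studies, cfg: TrainConfig, model: LASNet | None = None,
          model_config: LASNetConfig | None = None,
          callback=None):
    """Optimize the network on a list of DualStudy; returns (model, history).

    Fully seeded: the parameter init (via model_config.seed) and the
    patch sampling (cfg.seed) determine the loss curve exactly.
    """
    cfg.validate()
    if not studies:
        raise ValueError("need at least one study")
    if model is None:
        model = LASNet(model_config or LASNetConfig.test_profile())
    prepared = [prepare_study(s) for s in studies]
    rng = np.random.default_rng(cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = []
    queue: list = []
    for step in range(cfg.steps):
        opt.lr = nn.cosine_lr(step, cfg.steps, cfg.lr, warmup=cfg.warmup_steps,
                              floor=cfg.lr_floor)
        while len(queue) < cfg.batch_size:
            i = int(rng.integers(len(studies)))
            queue.extend(sample_patches(studies[i], cfg, rng, prepared[i]))
        batch = [queue.pop(0) for _ in range(cfg.batch_size)]
        x1 = Tensor(np.stack([b[0] for b in batch]))
        x2 = Tensor(np.stack([b[1] for b in batch]))
        y1 = np.stack([b[2] for b in batch])
        y2 = np.stack([b[3] for b in batch])
        logits1, logits2 = model.forward_tensors(x1, x2)
        loss = compound_loss(logits1, logits2, y1, y2, cfg)
        lval = loss.item()
        if not np.isfinite(lval):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={lval}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(lval)
        if callback is not None and callback(step, lval, model) is True:
            break  # early stop requested (e.g. a convergence target met)
    return model, history
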