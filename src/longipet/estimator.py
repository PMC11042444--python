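"""scikit-learn-style estimator facade over the dual-branch network.

``LASNetSegmenter`` wraps configuration, training and whole-volume
inference behind the familiar fit/predict surface so the model composes
with sklearn tooling (``get_params``/``set_params``, ``clone``).  ``X``
is a list of :class:`~longipet.phantom.DualStudy`; the reference masks
carried by the studies serve as ``y``, so ``fit`` accepts ``y=None``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import LASNet, LASNetConfig, predict_study
from .training import TrainConfig, train
from .inference_post import binarize

__all__ = ["LASNetSegmenter"]


class LASNetSegmenter(BaseEstimator):
    """Dual-time-point lesion segmenter.

    Parameters mirror the architecture and training configuration; the
    defaults are a reduced profile that trains on one CPU.  Fitted
    attributes: ``model_`` (the network), ``loss_curve_`` (per-step
    training loss), ``config_`` / ``train_config_``.
    """

    def __init__(self, *, embed_dim=12, depths=(1, 1), num_heads=(2, 4),
                 window_size=4, patch_size=(24, 24, 24), laag_kernel=7,
                 use_lawa=True, use_laag=True, use_pet1_branch=True,
                 steps=300, batch_size=2, lr=3e-3, weight_decay=1e-5,
                 fg_ratio=2.0 / 3.0, patches_per_volume=4,
                 ce_weight=1.0, dice_weight=1.0,
                 equivocal_policy="exclude_from_loss",
                 infer_roi=(32, 32, 32), overlap=0.25, threshold=0.5,
                 min_volume_ml=0.0, random_state=0):
        self.embed_dim = embed_dim
        self.depths = depths
        self.num_heads = num_heads
        self.window_size = window_size
        self.patch_size = patch_size
        self.laag_kernel = laag_kernel
        self.use_lawa = use_lawa
        self.use_laag = use_laag
        self.use_pet1_branch = use_pet1_branch
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.fg_ratio = fg_ratio
        self.patches_per_volume = patches_per_volume
        self.ce_weight = ce_weight
        self.dice_weight = dice_weight
        self.equivocal_policy = equivocal_policy
        self.infer_roi = infer_roi
        self.overlap = overlap
        self.threshold = threshold
        self.min_volume_ml = min_volume_ml
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self):
        mcfg = LASNetConfig(
            patch_size=tuple(self.patch_size), window_size=self.window_size,
            embed_dim=self.embed_dim, depths=tuple(self.depths),
            num_heads=tuple(self.num_heads), laag_kernel=self.laag_kernel,
            use_lawa=self.use_lawa, use_laag=self.use_laag,
            use_pet1_branch=self.use_pet1_branch, seed=self.random_state)
        tcfg = TrainConfig(
            steps=self.steps, batch_size=self.batch_size,
            patch_size=tuple(self.patch_size),
            patches_per_volume=self.patches_per_volume, fg_ratio=self.fg_ratio,
            lr=self.lr, weight_decay=self.weight_decay,
            ce_weight=self.ce_weight, dice_weight=self.dice_weight,
            equivocal_policy=self.equivocal_policy, seed=self.random_state)
        return mcfg, tcfg

    def fit(self, X, y=None, callback=None):
        """Train on a list of DualStudy (reference masks are the labels)."""
        mcfg, tcfg = self._configs()
        self.config_ = mcfg
        self.train_config_ = tcfg
        self.model_, self.loss_curve_ = train(
            list(X), tcfg, model_config=mcfg, callback=callback)
        return self

    def predict_proba_study(self, study):
        """Foreground probability volumes (prob1, prob2) for one study."""
        self._check_fitted()
        return predict_study(self.model_, study, roi=tuple(self.infer_roi),
                             overlap=self.overlap)

    def predict(self, X):
        """Binary (mask1, mask2) pairs for each study in X."""
        self._check_fitted()
        out = []
        for study in X:
            p1, p2 = self.predict_proba_study(study)
            out.append((
                binarize(p1, self.threshold, self.min_volume_ml, study.spacing_mm),
                binarize(p2, self.threshold, self.min_volume_ml, study.spacing_mm)))
        return out

    def score(self, X, y=None):
        """Mean PET1 Dice over studies (segmentation quality summary)."""
        from .evalstats import segmentation_scores

        dices = []
        for study, (m1, _) in zip(X, self.predict(X)):
            dices.append(segmentation_scores(
                m1, (study.mask1 > 0), study.spacing_mm)["dice"])
        return float(np.mean(dices))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
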