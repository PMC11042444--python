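"""Shared fixtures: phantom cohorts and (expensive) trained models.

The two training fixtures are session-scoped so the optimization cost is
paid once and shared between the unit suite and the acceptance suite.
"""

import numpy as np
import pytest

from longipet.phantom import PhantomSpec, ResponseModel, generate_cohort
from longipet.estimator import LASNetSegmenter
from longipet.evalstats import (
    match_overlap,
    paired_superiority,
    pooled_detection_f1,
    segmentation_scores,
)
from longipet.inference_post import extract_components


def _train_dice(est, studies):
    return float(np.mean([
        segmentation_scores(m1, s.mask1 > 0, s.spacing_mm)["dice"]
        for s, (m1, _) in zip(studies, est.predict(studies))]))


@pytest.fixture(scope="session")
def overfit_run():
    """Reduced-profile model memorising 4 phantom studies.

    Trains for at most 300 steps, checking the training PET1 Dice
    periodically and stopping once it comfortably clears 0.8.
    """
    spec = PhantomSpec.compact(
        response_model=ResponseModel(resolve_prob=0.5, new_lesion_prob=0.05))
    studies = generate_cohort(spec, 4, seed=13)
    est = LASNetSegmenter(steps=300, lr=3e-3, random_state=1)

    from longipet.model import LASNet
    from longipet.training import TrainConfig, train

    mcfg, tcfg = est._configs()
    state = {"steps": 0, "dice": 0.0}

    def stop_when_converged(step, loss, model):
        if (step + 1) % 75 == 0 and step + 1 < tcfg.steps:
            est.model_ = model
            d = _train_dice(est, studies)
            if d >= 0.82:
                state["steps"] = step + 1
                state["dice"] = d
                return True
        return None

    model, history = train(studies, tcfg, model_config=mcfg,
                           callback=stop_when_converged)
    est.model_ = model
    est.loss_curve_ = history
    if not state["steps"]:
        state["steps"] = len(history)
        state["dice"] = _train_dice(est, studies)
    return {"est": est, "studies": studies, "history": history,
            "steps": state["steps"], "dice1": state["dice"]}


@pytest.fixture(scope="session")
def ablation_run():
    """Scaled-down longitudinal-awareness comparison.

    A 24-phantom cohort with subtle residual uptake (median ~2 g/mL,
    overlapping the reference-region range); the full dual-branch model
    and the no-baseline-branch ablation are trained on 12 patients and
    compared on the other 12 by interim detection F1 under a paired
    patient-level bootstrap.
    """
    spec = PhantomSpec.compact(
        n_lesions_min=2, n_lesions_max=4,
        response_model=ResponseModel(resolve_prob=0.2, new_lesion_prob=0.05,
                                     shrink_factor=0.8, equivocal_prob=0.0))
    cohort = generate_cohort(spec, 24, seed=0)
    train_set, val_set = cohort[:12], cohort[12:]

    def detection_results(est):
        out = []
        for s, (_, m2) in zip(val_set, est.predict(val_set)):
            pc = extract_components(m2, s.pet2, s.spacing_mm)
            tc = extract_components(s.mask2, s.pet2, s.spacing_mm,
                                    reference_lesions=s.lesions2)
            out.append(match_overlap(pc, tc))
        return out

    common = dict(steps=300, lr=3e-3, random_state=0, infer_roi=(32, 32, 32))
    full = LASNetSegmenter(**common).fit(train_set)
    ablated = LASNetSegmenter(use_pet1_branch=False, **common).fit(train_set)
    res_full = detection_results(full)
    res_abl = detection_results(ablated)
    stat = lambda items: pooled_detection_f1(items)["f1"]
    comparison = paired_superiority(res_full, res_abl, statistic=stat,
                                    n_trials=2000, seed=5)
    return {
        "f1_full": stat(res_full),
        "f1_ablated": stat(res_abl),
        "superiority_fraction": comparison.superiority_fraction,
        "n_patients": len(val_set),
    }
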