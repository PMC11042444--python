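# longipet

Longitudinally-aware segmentation and quantification of serial PET/CT
scans in lymphoma.

## The problem

Interim FDG-PET response assessment in Hodgkin lymphoma compares a
baseline scan (PET1) against a scan taken after two chemotherapy cycles
(PET2).  Baseline disease is bulky and hot; residual interim disease is
faint (SUVmax ~ 2 g/mL) and hard to separate from physiologic uptake —
readers routinely look back at the baseline scan to decide what is
residual lymphoma.  Automated single-scan segmentation models inherit
none of that context and struggle on interim scans.

`longipet` implements a dual-branch segmentation network in which
baseline information flows — strictly one way — into the interim
analysis:

* a shared 3-D shifted-window transformer encoder / convolutional
  decoder backbone applied to both scans;
* **LAWA**: windowed multi-head cross-attention, queries from PET2
  features, keys/values from PET1 features, added residually to the
  PET2 stream at every encoder stage;
* **LAAG**: decoder attention gates whose PET2 coefficients are refined
  by a learnable 7×7×7 convolution over both branches' coefficients.

Around the network the package provides the full desk-scale workflow:
synthetic dual-time-point phantoms with known ground truth, training
with a compound cross-entropy + soft-Dice loss, sliding-window
inference, the MPDR false-positive filter (mask propagation through
registration), quantitative PET metrics (MTV, TLG, SUVmax, Dmax,
Dspleen, ΔSUVmax, qPET), qPET→Deauville conversion, lesion-level
detection scoring with equivocal-lesion exclusion, and patient-level
bootstrap statistics.  Everything runs on CPU through a self-contained
numpy autodiff engine — no deep-learning framework required.

Who it is for: researchers in quantitative PET/medical image analysis
who want a fully testable, dependency-light reference implementation of
longitudinal cross-attention segmentation and the associated response
metrics.

## Worked example

```python
from longipet import PhantomSpec, LASNetSegmenter, generate_cohort
from longipet.phantom import ResponseModel
from longipet.io import run_pipeline

spec = PhantomSpec.compact(
    n_lesions_min=2, n_lesions_max=4,
    response_model=ResponseModel(resolve_prob=0.2, new_lesion_prob=0.05,
                                 shrink_factor=0.8))
cohort = generate_cohort(spec, 8, seed=13)

est = LASNetSegmenter(steps=300, lr=3e-3, random_state=1).fit(cohort[:6])
scores = run_pipeline(cohort[6:], est.model_, "out/", use_mpdr=False, seed=1)
print(round(scores["pet1_dice_mean"], 3),
      round(scores["pet2_detection_overlap"]["f1"], 3))
```

On one CPU this trains the reduced-profile model (~8 minutes) and
prints the held-out baseline Dice and interim detection F1:

```
0.858 0.571
```

meaning the model segments the two held-out baseline scans with a mean
Dice of 0.858 and detects the faint residual interim lesions with an F1
of 0.571 at the overlap criterion — numbers from 2 small held-out
phantoms, so expect seed-to-seed variation.  The quantification table
(`out/cohort.csv`) holds per-patient MTV, TLG, SUVmax, Dmax, Dspleen,
ΔSUVmax, qPET and the derived Deauville band for both the prediction
and the reference masks.

A command-line surface wraps the same steps:

```bash
longipet phantom --n-patients 6 --seed 13 --out data/
longipet train --data data/ --out ckpt.npz --steps 300
longipet pipeline --data data/ --ckpt ckpt.npz --out results/
```

## Layout

| Module | Contents |
| --- | --- |
| `longipet.phantom` | synthetic dual-time-point studies, response model, NIfTI I/O |
| `longipet.nn` | numpy autodiff engine, layers, AdamW |
| `longipet.model` | the dual-branch network (LAWA, LAAG), sliding-window inference |
| `longipet.training` | compound loss, patch sampling, folds, training loop |
| `longipet.estimator` | `LASNetSegmenter`, the sklearn-style facade |
| `longipet.inference_post` | components, binarization, MPDR filter |
| `longipet.quant` | MTV/TLG/SUVmax/Dmax/Dspleen/ΔSUVmax/qPET, Deauville |
| `longipet.evalstats` | detection matching, Dice/FPV/FNV, kappa, bootstrap |
| `longipet.io`, `longipet.cli` | volumes, manifests, pipeline, CLI verbs |

See `docs/methods.md` for the model, conventions and limitations.
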