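"""Volume I/O, cohort manifests, and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import DualStudy, read_study
from .model import LASNet
from .inference_post import binarize, extract_components, mpdr_filter
from .quant import quantify_study
from .evalstats import (
    match_overlap, match_suvmax, pooled_detection_f1, segmentation_scores,
    ds_agreement,
)

log = logging.getLogger("longipet")

__all__ = [
    "read_volume",
    "write_volume",
    "CohortManifest",
    "run_pipeline",
    "config_hash",
]


def read_volume(path: str | Path):
    """Load a 3-D NIfTI volume; returns (array, affine)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    nib.save(nib.Nifti1Image(data, affine), str(path))


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for provenance logs."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


class CohortManifest:
    """Table of per-patient study directories (written by the phantom
    module), with optional fold assignments."""

    def __init__(self, rows: list[dict]):
        ids = [r["patient_id"] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in manifest")
        self.rows = rows

    @classmethod
    def from_directory(cls, root: str | Path) -> "CohortManifest":
        root = Path(root)
        rows = []
        for d in sorted(p for p in root.iterdir() if p.is_dir()):
            if (d / "lesions.json").exists():
                rows.append({"patient_id": d.name, "path": str(d)})
        if not rows:
            raise FileNotFoundError(f"no study directories under {root}")
        return cls(rows)

    def load_studies(self) -> list[DualStudy]:
        return [read_study(r["path"]) for r in self.rows]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows).to_csv(path, index=False)

    def __len__(self):
        return len(self.rows)


def run_pipeline(studies: list[DualStudy], model: LASNet, out_dir: str | Path,
                 use_mpdr: bool = False, threshold: float = 0.5,
                 overlap: float = 0.25, roi=None, seed: int = 0) -> dict:
    """predict -> (optional MPDR) -> quantify -> evaluate for a cohort.

    Writes per-patient quantification JSON, a cohort CSV and a score
    JSON under ``out_dir``; per-patient failures are isolated and
    reported in the returned summary.
    """
    from .model import predict_study

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(model.config)
    log.info("pipeline start: %d patients, config %s, seed %d",
             len(studies), chash, seed)

    rows, failures = [], []
    match_o, match_s, seg = [], [], []
    pred_ds, true_ds = [], []
    for study in studies:
        try:
            p1, p2 = predict_study(model, study, roi=roi, overlap=overlap)
            m1 = binarize(p1, threshold, spacing=study.spacing_mm)
            m2 = binarize(p2, threshold, spacing=study.spacing_mm)
            audit = None
            if use_mpdr:
                m2, audit = mpdr_filter(m1, m2)
            c1 = extract_components(m1, study.pet1, study.spacing_mm)
            c2 = extract_components(m2, study.pet2, study.spacing_mm)
            t1 = extract_components(study.mask1, study.pet1, study.spacing_mm,
                                    reference_lesions=study.lesions1)
            t2 = extract_components(study.mask2, study.pet2, study.spacing_mm,
                                    reference_lesions=study.lesions2)
            report = quantify_study(c1, c2, study.pet2, study.organs,
                                    study.spacing_mm, study.patient_id)
            ref_report = quantify_study(t1, t2, study.pet2, study.organs,
                                        study.spacing_mm, study.patient_id)
            match_o.append(match_overlap(c2, t2))
            match_s.append(match_suvmax(c2, t2))
            seg.append(segmentation_scores(m1, study.mask1 > 0, study.spacing_mm))
            pred_ds.append(report.ds_band)
            true_ds.append(ref_report.ds_band)
            row = report.to_row()
            row.update({f"ref_{k}": v for k, v in ref_report.to_row().items()
                        if k != "patient_id"})
            rows.append(row)
            payload = {"prediction": report.to_row(), "reference": ref_report.to_row(),
                       "config_hash": chash, "seed": seed}
            if audit is not None:
                payload["mpdr"] = {"kept": audit.kept, "removed": audit.removed}
            (out_dir / f"{study.patient_id}_quant.json").write_text(
                json.dumps(payload, indent=1, default=float))
        except Exception as e:  # noqa: BLE001 - per-patient isolation
            log.exception("patient %s failed", study.patient_id)
            failures.append({"patient_id": study.patient_id, "error": str(e)})

    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    scores = {
        "config_hash": chash,
        "seed": seed,
        "n_patients": len(rows),
        "failures": failures,
        "pet2_detection_overlap": pooled_detection_f1(match_o),
        "pet2_detection_suvmax": pooled_detection_f1(match_s),
        "pet1_dice_mean": float(np.mean([s["dice"] for s in seg])) if seg else None,
        "pet1_fpv_mean_ml": float(np.mean([s["fpv_ml"] for s in seg])) if seg else None,
        "pet1_fnv_mean_ml": float(np.mean([s["fnv_ml"] for s in seg])) if seg else None,
        "ds_agreement_3plus": ds_agreement(pred_ds, true_ds, 3) if rows else None,
        "ds_agreement_4plus": ds_agreement(pred_ds, true_ds, 4) if rows else None,
    }
    (out_dir / "scores.json").write_text(json.dumps(scores, indent=1, default=float))
    if failures:
        log.warning("%d patients failed", len(failures))
    return scores
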