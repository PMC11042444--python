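"""Quantitative PET metrics and the qPET -> Deauville conversion.

Baseline (PET1) metrics: metabolic tumor volume (MTV, mL), total lesion
glycolysis (TLG, mL*g/mL), SUVmax, maximum tumor dissemination (Dmax,
mm, between lesion centroids), maximum lesion-to-spleen distance
(Dspleen, mm, centroid to nearest spleen surface voxel), lesion count.

Interim (PET2) metrics: SUVmax, percent change from baseline SUVmax
(dSUVmax), qPET (hottest residual lesion SUVpeak divided by mean liver
SUV) and the residual-lesion count.  qPET maps onto Deauville bands via
fixed cut points; the patient-level Deauville score is alternatively
the maximum lesion-level score.

Conventions when no residual lesion is segmented: SUVmax2 = 0, dSUVmax
= -100%, qPET = 0 with a no-lesion flag, Deauville band "<=2".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy import ndimage

from .inference_post import LesionComponent

__all__ = [
    "QuantReport",
    "compute_mtv",
    "compute_tlg",
    "compute_suvmax",
    "compute_dmax",
    "compute_dspleen",
    "compute_delta_suvmax",
    "compute_qpet",
    "qpet_to_ds",
    "patient_ds",
    "ds_band_positive",
    "quantify_study",
    "DS_BAND_LE2",
    "QPET_CUTS",
]

DS_BAND_LE2 = "<=2"

# qPET cut points mapping the liver-normalised peak onto Deauville bands
QPET_CUTS = {"t23": 0.95, "t34": 1.3, "t45": 2.0}


def compute_mtv(components: list[LesionComponent]) -> float:
    """Total segmented volume in mL."""
    return float(sum(c.volume_ml for c in components))


def compute_tlg(components: list[LesionComponent]) -> float:
    """SUV-weighted volume: sum over lesions of MTV_l * SUVmean_l."""
    return float(sum(c.volume_ml * c.suvmean for c in components))


def compute_suvmax(components: list[LesionComponent]) -> float:
    return float(max((c.suvmax for c in components), default=0.0))


def compute_dmax(components: list[LesionComponent]) -> float:
    """Largest centroid-to-centroid distance (mm); 0 with <= 1 lesion."""
    if len(components) <= 1:
        return 0.0
    pts = np.array([c.centroid_mm for c in components])
    d2 = ((pts[:, None] - pts[None]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def compute_dspleen(components: list[LesionComponent], spleen_mask: np.ndarray,
                    spacing) -> float:
    """Max over lesions of centroid distance to the nearest spleen-surface
    voxel (mm); 0 without lesions."""
    if not spleen_mask.any():
        raise ValueError("spleen mask is empty")
    if not components:
        return 0.0
    surf = _surface_voxels(spleen_mask.astype(bool))
    if len(surf) == 0:  # single-voxel spleen has no erodable interior
        surf = np.argwhere(spleen_mask)
    shape = spleen_mask.shape
    surf_mm = (surf - (np.array(shape) - 1) / 2.0) * np.array(spacing)
    tree = cKDTree(surf_mm)
    dists = [tree.query(np.array(c.centroid_mm))[0] for c in components]
    # a centroid inside the spleen is at distance 0, not surface distance
    out = []
    for c, d in zip(components, dists):
        vox = np.round(np.array(c.centroid_mm) / np.array(spacing)
                       + (np.array(shape) - 1) / 2.0).astype(int)
        vox = np.clip(vox, 0, np.array(shape) - 1)
        inside = bool(spleen_mask[tuple(vox)])
        out.append(0.0 if inside else float(d))
    return float(max(out))


def compute_delta_suvmax(suvmax1: float, suvmax2: float) -> float | None:
    """Percent change; None (missing) when the baseline value is not
    positive; -100 when nothing residual is segmented."""
    if suvmax1 <= 0:
        return None
    return 100.0 * (suvmax2 - suvmax1) / suvmax1


def compute_qpet(components2: list[LesionComponent], liver_mask: np.ndarray,
                 pet2: np.ndarray) -> tuple[float, bool]:
    """qPET = SUVpeak of the hottest residual lesion / mean liver SUV.

    Returns (qpet, no_lesion_flag); (0.0, True) without residual lesions.
    """
    if not liver_mask.any():
        raise ValueError("liver mask is empty")
    if not components2:
        return 0.0, True
    liver_mean = float(pet2[liver_mask.astype(bool)].mean())
    hottest = max(components2, key=lambda c: c.suvpeak)
    return float(hottest.suvpeak / liver_mean), False


def qpet_to_ds(qpet: float, cuts: dict | None = None) -> str:
    """Map qPET onto Deauville bands with half-open intervals
    [t23,t34) -> 3, [t34,t45) -> 4, >= t45 -> 5; below t23 -> "<=2"."""
    c = cuts or QPET_CUTS
    if qpet < c["t23"]:
        return DS_BAND_LE2
    if qpet < c["t34"]:
        return "3"
    if qpet < c["t45"]:
        return "4"
    return "5"


def patient_ds(components2: list[LesionComponent]) -> str:
    """Patient-level Deauville score = highest lesion-level score."""
    scores = [c.lds for c in components2 if c.lds is not None]
    if not scores:
        return DS_BAND_LE2
    m = max(scores)
    return DS_BAND_LE2 if m <= 2 else str(m)


def ds_band_positive(ds: str, threshold: int) -> bool:
    """Inadequate-response positivity at DS >= threshold (3 or 4)."""
    if ds == DS_BAND_LE2:
        return False
    return int(ds) >= threshold


@dataclass
class QuantReport:
    patient_id: str
    mtv_ml: float
    tlg: float
    suvmax1: float
    dmax_mm: float
    dspleen_mm: float | None
    n_lesions1: int
    suvmax2: float
    delta_suvmax_pct: float | None
    qpet: float | None
    qpet_no_lesion: bool
    n_lesions2: int
    ds_band: str
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mtv_ml": self.mtv_ml, "tlg": self.tlg, "suvmax1": self.suvmax1,
            "dmax_mm": self.dmax_mm, "dspleen_mm": self.dspleen_mm,
            "n_lesions1": self.n_lesions1, "suvmax2": self.suvmax2,
            "delta_suvmax_pct": self.delta_suvmax_pct, "qpet": self.qpet,
            "n_lesions2": self.n_lesions2, "ds_band": self.ds_band,
        }


def quantify_study(components1: list[LesionComponent],
                   components2: list[LesionComponent],
                   pet2: np.ndarray,
                   organs: np.ndarray | None,
                   spacing,
                   patient_id: str = "unknown",
                   qpet_cuts: dict | None = None) -> QuantReport:
    """Full metric panel for one patient.

    ``organs`` supplies liver (qPET) and spleen (Dspleen) masks; when it
    is missing those metrics are reported as missing and everything else
    is still computed.
    """
    from .phantom import ORGAN_LABELS

    suvmax1 = compute_suvmax(components1)
    suvmax2 = compute_suvmax(components2)
    dspleen = None
    qpet = None
    flag = len(components2) == 0
    if organs is not None:
        spleen = organs == ORGAN_LABELS["spleen"]
        liver = organs == ORGAN_LABELS["liver"]
        if spleen.any():
            dspleen = compute_dspleen(components1, spleen, spacing)
        if liver.any():
            qpet, flag = compute_qpet(components2, liver, pet2)
    return QuantReport(
        patient_id=patient_id,
        mtv_ml=compute_mtv(components1),
        tlg=compute_tlg(components1),
        suvmax1=suvmax1,
        dmax_mm=compute_dmax(components1),
        dspleen_mm=dspleen,
        n_lesions1=len(components1),
        suvmax2=suvmax2,
        delta_suvmax_pct=compute_delta_suvmax(suvmax1, suvmax2),
        qpet=qpet,
        qpet_no_lesion=flag,
        n_lesions2=len(components2),
        ds_band=qpet_to_ds(qpet, qpet_cuts) if qpet is not None else DS_BAND_LE2,
    )
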