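"""Synthetic dual-time-point PET/CT phantoms with known lesion ground truth.

Each phantom patient is a pair of co-registered scans: a baseline scan
(PET1) carrying bulky, hot lymphoma lesions, and an interim scan (PET2)
in which most lesions have resolved and the survivors show faint
residual uptake, occasionally joined by new lesions absent at baseline.
The body contains the three reference regions that Deauville-style
response scoring relies on (liver, mediastinal blood pool, spleen), so
lesion-level Deauville scores (LDS) can be assigned from simulated
uptake exactly the way a reader grades residual disease: above
mediastinum but at most liver -> LDS 3, above liver -> LDS 4, far above
liver -> LDS 5.

Default calibration targets the lesion statistics of a high-risk
pediatric Hodgkin lymphoma cohort: baseline lesion SUVmax with median
about 13 g/mL and a total baseline MTV median of a few hundred mL;
residual interim lesions with SUVmax median about 2 g/mL, of which
roughly one in five is flagged equivocal.

The generator is fully deterministic: every draw flows through one
`numpy.random.Generator` seeded from (seed, patient index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "OrganParams",
    "ResponseModel",
    "PhantomSpec",
    "LesionMeta",
    "DualStudy",
    "generate_study",
    "generate_cohort",
    "simulate_response",
    "make_displacement_field",
    "warp_volume",
    "apply_misalignment",
    "write_study",
    "read_study",
    "ORGAN_LABELS",
]

ORGAN_LABELS = {"body": 1, "liver": 2, "mediastinum": 3, "spleen": 4}


class PhantomValidationError(ValueError):
    """A PhantomSpec field violates an invariant; the message names it."""


@dataclass
class OrganParams:
    """Ellipsoidal organ: center offset from volume center (mm), radii (mm)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    mean_suv: float
    noise_sd: float


@dataclass
class ResponseModel:
    """Per-lesion stochastic model of interim response.

    Most baseline lesions resolve completely; survivors shrink and their
    uptake falls to the residual scale.  A residual whose simulated peak
    stays at or below mediastinal blood pool is treated as resolved for
    annotation purposes (readers only contour LDS >= 3 disease).
    """

    resolve_prob: float = 0.75
    residual_suvmax_median: float = 2.0
    residual_suvmax_sigma: float = 0.45
    shrink_factor: float = 0.55
    new_lesion_prob: float = 0.05
    equivocal_prob: float = 0.2
    lds5_liver_factor: float = 2.0
    # Visual grading compares uptake to the reference regions with some
    # reader variability; without it, the contoured (LDS >= 3) subset is
    # sharply truncated at mediastinal uptake.
    grading_jitter_sd: float = 0.15

    @property
    def residual_draw_median(self) -> float:
        """Median of the raw residual-uptake draw.

        Set below ``residual_suvmax_median`` so that after the LDS >= 3
        annotation cut (readers only contour supra-mediastinal disease)
        the *contoured* lesions have the target SUVmax median.
        """
        return 0.75 * self.residual_suvmax_median


def _default_organs() -> dict[str, OrganParams]:
    return {
        "body": OrganParams((0.0, 0.0, 0.0), (150.0, 160.0, 180.0), 0.7, 0.10),
        "liver": OrganParams((55.0, 40.0, -40.0), (55.0, 45.0, 40.0), 2.2, 0.15),
        "mediastinum": OrganParams((0.0, -10.0, 60.0), (22.0, 22.0, 60.0), 1.6, 0.10),
        "spleen": OrganParams((-60.0, 35.0, -45.0), (30.0, 25.0, 35.0), 1.8, 0.12),
    }


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    organ_params: dict[str, OrganParams] = field(default_factory=_default_organs)
    n_lesions_min: int = 2
    n_lesions_max: int = 6
    lesion_radius_mm_median: float = 30.0
    lesion_radius_sigma: float = 0.30
    baseline_suvmax_median: float = 13.0
    baseline_suvmax_sigma: float = 0.33
    response_model: ResponseModel = field(default_factory=ResponseModel)
    misalignment_mm: float = 4.0
    voxel_noise_sd: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        for name, org in self.organ_params.items():
            if any(r <= 0 for r in org.radii_mm):
                raise PhantomValidationError(
                    f"organ_params[{name!r}].radii_mm must be positive, got {org.radii_mm}")
        body = self.organ_params["body"]
        for name, org in self.organ_params.items():
            if name == "body":
                continue
            for c, r, br in zip(org.center_mm, org.radii_mm, body.radii_mm):
                if abs(c) + r > br:
                    raise PhantomValidationError(
                        f"organ_params[{name!r}] extends outside the body along an axis")
        op = self.organ_params
        if not (op["liver"].mean_suv > op["mediastinum"].mean_suv > op["body"].mean_suv):
            raise PhantomValidationError(
                "organ_params must satisfy liver SUV > mediastinum SUV > body SUV")
        if self.n_lesions_min < 0 or self.n_lesions_max < self.n_lesions_min:
            raise PhantomValidationError("n_lesions_min/max must be 0 <= min <= max")
        if self.lesion_radius_mm_median <= 0:
            raise PhantomValidationError("lesion_radius_mm_median must be positive")
        if self.misalignment_mm < 0:
            raise PhantomValidationError("misalignment_mm must be >= 0")

    @classmethod
    def compact(cls, **overrides) -> "PhantomSpec":
        """A small-grid profile (32^3 at 6 mm) for fast CPU work.

        The body and organs are scaled to fit the 192 mm field of view;
        lesion size is scaled accordingly.  Uptake calibration (SUV
        medians) is unchanged.
        """
        s = 0.5  # spatial scale relative to the default 384 mm FOV
        organs = {
            name: OrganParams(
                tuple(c * s for c in org.center_mm),
                tuple(r * s for r in org.radii_mm),
                org.mean_suv, org.noise_sd)
            for name, org in _default_organs().items()
        }
        params = dict(
            grid_shape=(32, 32, 32),
            voxel_spacing_mm=(6.0, 6.0, 6.0),
            organ_params=organs,
            n_lesions_min=1,
            n_lesions_max=3,
            lesion_radius_mm_median=14.0,
            misalignment_mm=3.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class LesionMeta:
    label: int
    lds: int | None = None       # 1..5; only meaningful for interim lesions
    equivocal: bool = False
    is_new: bool = False
    centroid_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    suvmax_true: float = 0.0

    def to_json(self) -> dict:
        return {
            "label": int(self.label),
            "lds": None if self.lds is None else int(self.lds),
            "equivocal": bool(self.equivocal),
            "is_new": bool(self.is_new),
            "centroid_mm": [float(c) for c in self.centroid_mm],
            "suvmax_true": float(self.suvmax_true),
        }

    @classmethod
    def from_json(cls, d: dict) -> "LesionMeta":
        return cls(d["label"], d["lds"], d["equivocal"], d["is_new"],
                   tuple(d["centroid_mm"]), d.get("suvmax_true", 0.0))


@dataclass
class DualStudy:
    pet1: np.ndarray
    ct1: np.ndarray
    pet2: np.ndarray
    ct2: np.ndarray
    mask1: np.ndarray            # labelled, 0 background
    mask2: np.ndarray
    organs: np.ndarray           # ORGAN_LABELS codes
    lesions1: list[LesionMeta]
    lesions2: list[LesionMeta]
    spacing_mm: tuple[float, float, float]
    patient_id: str = "phantom"


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _grid_mm(shape, spacing):
    """Physical coordinates of voxel centers, origin at volume center.

    Returned as broadcastable 1-D axes (sparse meshgrid) so ellipsoid
    membership tests stay cheap.
    """
    axes = [(np.arange(n) - (n - 1) / 2.0) * sp for n, sp in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(coords, center_mm, radii_mm) -> np.ndarray:
    q = sum(((c - cc) / r) ** 2 for c, cc, r in zip(coords, center_mm, radii_mm))
    return q <= 1.0


def _smooth_profile(mask: np.ndarray, spacing, edge_mm: float = 4.0) -> np.ndarray:
    """Soft version of a binary mask, renormalised so its max is 1."""
    sig = [edge_mm / sp for sp in spacing]
    prof = ndimage.gaussian_filter(mask.astype(np.float32), sig)
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def _bbox_slices(mask: np.ndarray, margin: int) -> tuple:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


@dataclass
class _Lesion:
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float


def _draw_lesion_geometry(spec: PhantomSpec, rng: np.random.Generator,
                          radius_scale: float = 1.0) -> tuple:
    body = spec.organ_params["body"]
    r = float(np.exp(rng.normal(np.log(spec.lesion_radius_mm_median),
                                spec.lesion_radius_sigma))) * radius_scale
    radii = tuple(r * float(f) for f in rng.uniform(0.75, 1.25, size=3))
    for _ in range(100):
        u = rng.uniform(-1.0, 1.0, size=3)
        cand = tuple(u[i] * (body.radii_mm[i] - radii[i] - 8.0) for i in range(3))
        q = sum(((cand[i] + radii[i] * np.sign(cand[i])) / body.radii_mm[i]) ** 2
                for i in range(3))
        if q <= 0.92:
            return cand, radii
    return (0.0, 0.0, 0.0), radii


def _render_lesions(pet: np.ndarray, coords, lesions: list[_Lesion], spacing,
                    mask_threshold: float = 0.5):
    """Paint lesions onto a PET background; returns labelled mask."""
    mask = np.zeros(pet.shape, dtype=np.int16)
    for i, les in enumerate(lesions, start=1):
        hard = _ellipsoid(coords, les.center_mm, les.radii_mm)
        if not hard.any():
            continue
        sl = _bbox_slices(hard, margin=4)
        prof = _smooth_profile(hard[sl], spacing)
        np.maximum(pet[sl], prof * les.peak_suv, out=pet[sl])
        mask[sl][prof > mask_threshold] = i
    return mask


def _background(spec: PhantomSpec, coords, rng: np.random.Generator):
    """Organ-labelled SUV background and a CT-like density channel."""
    shape = spec.grid_shape
    organs = np.zeros(shape, dtype=np.int16)
    pet = np.full(shape, 0.05, dtype=np.float32)
    ct = np.full(shape, -1000.0, dtype=np.float32)
    ct_values = {"body": 40.0, "liver": 60.0, "mediastinum": 45.0, "spleen": 55.0}
    smooth_noise = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=shape).astype(np.float32), 1.0) * 3.0
    for name in ["body", "liver", "mediastinum", "spleen"]:
        org = spec.organ_params[name]
        m = _ellipsoid(coords, org.center_mm, org.radii_mm)
        organs[m] = ORGAN_LABELS[name]
        pet[m] = org.mean_suv + smooth_noise[m] * org.noise_sd
        ct[m] = ct_values[name]
    ct = ndimage.gaussian_filter(ct, 1.0)
    return organs, pet, ct


def _finalize_pet(pet: np.ndarray, body: np.ndarray, rng: np.random.Generator,
                  noise_sd: float) -> np.ndarray:
    pet = pet + rng.normal(0.0, noise_sd, size=pet.shape).astype(np.float32)
    np.clip(pet, 0.01, None, out=pet)
    pet[~body] = np.clip(pet[~body], 0.01, 0.15)
    return pet.astype(np.float32)


def _centroid_mm(mask: np.ndarray, label: int, spacing) -> tuple:
    idx = np.argwhere(mask == label)
    if idx.size == 0:
        return (0.0, 0.0, 0.0)
    shape = mask.shape
    c = idx.mean(axis=0)
    return tuple(float((c[i] - (shape[i] - 1) / 2.0) * spacing[i]) for i in range(3))


# ----------------------------------------------------------------------
# response simulation
# ----------------------------------------------------------------------

def _assign_lds(peak_suv: float, mediastinum_suv: float, liver_suv: float,
                lds5_factor: float, jitter: float = 1.0) -> int:
    """Deauville-style grading of residual uptake against reference regions.

    ``jitter`` multiplies the reference levels, emulating reader
    variability in the visual comparison.
    """
    med = mediastinum_suv * jitter
    liv = liver_suv * jitter
    if peak_suv > liv * lds5_factor:
        return 5
    if peak_suv > liv:
        return 4
    if peak_suv > med:
        return 3
    return 2


def simulate_response(baseline_lesions: list[_Lesion], spec: PhantomSpec,
                      rng: np.random.Generator):
    """Derive the interim lesion set from the baseline one.

    Returns (rendered lesions, metadata prototypes) where metadata holds
    (lds, equivocal, is_new, annotated).  Only annotated lesions (LDS >=
    3) enter the reference mask; sub-mediastinal residuals stay visible
    in the image but carry no contour, mirroring reader behaviour.
    """
    rm = spec.response_model
    med_suv = spec.organ_params["mediastinum"].mean_suv
    liver_suv = spec.organ_params["liver"].mean_suv
    rendered: list[_Lesion] = []
    meta: list[dict] = []
    for les in baseline_lesions:
        if rng.uniform() < rm.resolve_prob:
            continue
        peak = float(np.exp(rng.normal(np.log(rm.residual_draw_median),
                                       rm.residual_suvmax_sigma)))
        radii = tuple(r * rm.shrink_factor for r in les.radii_mm)
        jit = float(np.exp(rng.normal(0.0, rm.grading_jitter_sd)))
        lds = _assign_lds(peak, med_suv, liver_suv, rm.lds5_liver_factor, jit)
        annotated = lds >= 3
        rendered.append(_Lesion(les.center_mm, radii, peak))
        meta.append(dict(lds=lds, equivocal=bool(rng.uniform() < rm.equivocal_prob),
                         is_new=False, annotated=annotated))
    if rng.uniform() < rm.new_lesion_prob:
        center, radii = _draw_lesion_geometry(spec, rng, radius_scale=rm.shrink_factor)
        # a reported new lesion must be conspicuous: above mediastinal uptake
        peak = med_suv * float(np.exp(rng.uniform(np.log(1.2), np.log(2.5))))
        lds = _assign_lds(peak, med_suv, liver_suv, rm.lds5_liver_factor)
        rendered.append(_Lesion(center, radii, peak))
        meta.append(dict(lds=max(lds, 3), equivocal=False, is_new=True, annotated=True))
    return rendered, meta


# ----------------------------------------------------------------------
# misalignment
# ----------------------------------------------------------------------

def make_displacement_field(shape, spacing, magnitude_mm: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement (voxel units), shape (3, D, H, W).

    A coarse 4^3 grid of random offsets is upsampled with cubic
    interpolation and combined with a small rigid shift; each component
    is clamped so no voxel moves farther than ``magnitude_mm``.
    """
    if magnitude_mm == 0:
        return np.zeros((3,) + tuple(shape), dtype=np.float32)
    field = np.empty((3,) + tuple(shape), dtype=np.float32)
    rigid = rng.uniform(-magnitude_mm / 3.0, magnitude_mm / 3.0, size=3)
    for ax in range(3):
        # smooth at coarse resolution (cheap), then upsample linearly
        coarse = rng.normal(0.0, magnitude_mm, size=(8, 8, 8))
        coarse = ndimage.gaussian_filter(coarse, 1.5)
        zoom = [s / 8.0 for s in shape]
        smooth = ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)
        disp_mm = np.clip(smooth + rigid[ax], -magnitude_mm, magnitude_mm)
        field[ax] = disp_mm / spacing[ax]
    return field


def warp_volume(vol: np.ndarray, field: np.ndarray, order: int = 1,
                cval: float = 0.0) -> np.ndarray:
    """Pull-back warp: out(x) = vol(x + d(x)); order=0 for label maps."""
    idx = np.indices(vol.shape).astype(np.float32)
    coords = idx + field
    return ndimage.map_coordinates(vol.astype(np.float32), coords, order=order,
                                   mode="constant", cval=cval).astype(vol.dtype)


def apply_misalignment(volumes: dict, magnitude_mm: float, spacing,
                       rng: np.random.Generator) -> dict:
    """Warp a set of interim volumes with one shared displacement field.

    ``volumes`` maps names to arrays; keys containing 'mask' are warped
    with nearest-neighbour interpolation to keep labels intact.  With
    magnitude 0 the input is returned unchanged.
    """
    if magnitude_mm == 0:
        return dict(volumes)
    shape = next(iter(volumes.values())).shape
    field = make_displacement_field(shape, spacing, magnitude_mm, rng)
    out = {}
    for name, vol in volumes.items():
        if "mask" in name or "organ" in name:
            out[name] = warp_volume(vol, field, order=0)
        else:
            out[name] = warp_volume(vol, field, order=1, cval=float(np.median(vol)))
    return out


# ----------------------------------------------------------------------
# study generation
# ----------------------------------------------------------------------

def generate_study(spec: PhantomSpec, seed: int | None = None,
                   patient_id: str = "phantom") -> DualStudy:
    """Generate one dual-time-point study from a validated spec."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    spacing = spec.voxel_spacing_mm
    coords = _grid_mm(spec.grid_shape, spacing)

    # ---- baseline -----------------------------------------------------
    organs, pet1_bg, ct1 = _background(spec, coords, rng)
    n_lesions = int(rng.integers(spec.n_lesions_min, spec.n_lesions_max + 1))
    baseline_lesions = []
    for _ in range(n_lesions):
        center, radii = _draw_lesion_geometry(spec, rng)
        peak = float(np.exp(rng.normal(np.log(spec.baseline_suvmax_median),
                                       spec.baseline_suvmax_sigma)))
        baseline_lesions.append(_Lesion(center, radii, peak))
    pet1 = pet1_bg.copy()
    mask1 = _render_lesions(pet1, coords, baseline_lesions, spacing)
    body = organs > 0
    pet1 = _finalize_pet(pet1, body, rng, spec.voxel_noise_sd)
    lesions1 = [
        LesionMeta(label=i, lds=None, equivocal=False, is_new=False,
                   centroid_mm=_centroid_mm(mask1, i, spacing),
                   suvmax_true=baseline_lesions[i - 1].peak_suv)
        for i in range(1, n_lesions + 1) if (mask1 == i).any()
    ]

    # ---- interim ------------------------------------------------------
    organs2, pet2_bg, ct2 = _background(spec, coords, rng)
    rendered, meta = simulate_response(baseline_lesions, spec, rng)
    pet2 = pet2_bg.copy()
    full_mask2 = _render_lesions(pet2, coords, rendered, spacing)
    pet2 = _finalize_pet(pet2, body, rng, spec.voxel_noise_sd)

    # keep only annotated residuals in the reference mask, relabelled 1..K
    mask2 = np.zeros_like(full_mask2)
    lesions2: list[LesionMeta] = []
    next_label = 1
    for i, m in enumerate(meta, start=1):
        voxels = full_mask2 == i
        if not m["annotated"] or not voxels.any():
            continue
        mask2[voxels] = next_label
        lesions2.append(LesionMeta(
            label=next_label, lds=m["lds"], equivocal=m["equivocal"],
            is_new=m["is_new"], centroid_mm=_centroid_mm(mask2, next_label, spacing),
            suvmax_true=rendered[i - 1].peak_suv))
        next_label += 1

    warped = apply_misalignment(
        {"pet2": pet2, "ct2": ct2, "mask2": mask2},
        spec.misalignment_mm, spacing, rng)
    pet2, ct2, mask2 = warped["pet2"], warped["ct2"], warped["mask2"]
    np.clip(pet2, 0.01, None, out=pet2)
    mask2[organs == 0] = 0  # annotation never leaves the body
    # misalignment may (rarely) wipe a small lesion off the grid
    surviving = np.unique(mask2)
    lesions2 = [l for l in lesions2 if l.label in surviving]
    for l in lesions2:
        l.centroid_mm = _centroid_mm(mask2, l.label, spacing)

    return DualStudy(pet1=pet1, ct1=ct1, pet2=pet2.astype(np.float32),
                     ct2=ct2.astype(np.float32), mask1=mask1, mask2=mask2,
                     organs=organs, lesions1=lesions1, lesions2=lesions2,
                     spacing_mm=spacing, patient_id=patient_id)


def generate_cohort(spec: PhantomSpec, n_patients: int, seed: int) -> list[DualStudy]:
    """Generate a cohort; each patient has an independent substream."""
    studies = []
    for i in range(n_patients):
        child = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        studies.append(generate_study(spec, seed=int(child), patient_id=f"p{i:03d}"))
    return studies


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_study(study: DualStudy, directory: str | Path) -> list[Path]:
    """Write NIfTI volumes plus a JSON lesion sidecar; see read_study."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.spacing_mm)
    written = []
    for name in ["pet1", "ct1", "pet2", "ct2"]:
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(study, name).astype(np.float32), aff), p)
        written.append(p)
    for name in ["mask1", "mask2", "organs"]:
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(study, name).astype(np.int16), aff), p)
        written.append(p)
    sidecar = directory / "lesions.json"
    sidecar.write_text(json.dumps({
        "patient_id": study.patient_id,
        "spacing_mm": list(study.spacing_mm),
        "lesions1": [l.to_json() for l in study.lesions1],
        "lesions2": [l.to_json() for l in study.lesions2],
    }, indent=1))
    written.append(sidecar)
    return written


def read_study(directory: str | Path) -> DualStudy:
    import nibabel as nib

    directory = Path(directory)
    vols = {}
    for name in ["pet1", "ct1", "pet2", "ct2", "mask1", "mask2", "organs"]:
        p = directory / f"{name}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"missing volume: {p}")
        img = nib.load(p)
        data = np.asarray(img.dataobj)
        vols[name] = data.astype(np.int16) if name.startswith(("mask", "organ")) \
            else data.astype(np.float32)
    meta = json.loads((directory / "lesions.json").read_text())
    return DualStudy(
        pet1=vols["pet1"], ct1=vols["ct1"], pet2=vols["pet2"], ct2=vols["ct2"],
        mask1=vols["mask1"], mask2=vols["mask2"], organs=vols["organs"],
        lesions1=[LesionMeta.from_json(d) for d in meta["lesions1"]],
        lesions2=[LesionMeta.from_json(d) for d in meta["lesions2"]],
        spacing_mm=tuple(meta["spacing_mm"]), patient_id=meta["patient_id"])
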