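"""From probability maps to lesion components, plus the MPDR filter.

MPDR (mask propagation through deformable registration) reduces false
positives on the interim scan: the baseline prediction is propagated
onto the interim grid and every interim component with no voxel overlap
against the propagated mask is discarded.  The filter can only remove
components — it never adds voxels — and it is idempotent.  Its known
cost is that genuinely new interim lesions (absent at baseline) are
removed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionComponent",
    "extract_components",
    "binarize",
    "mpdr_filter",
    "MPDRAudit",
    "RegistrationError",
    "identity_transform",
    "rigid_shift_transform",
    "displacement_transform",
    "register_deformable",
]

# 26-connectivity: PET lesions are conventionally treated as connected
# across faces, edges and corners
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class RegistrationError(RuntimeError):
    """Raised when mask propagation cannot be performed; never silently
    replaced by an identity fallback."""


@dataclass
class LesionComponent:
    label: int
    voxels: np.ndarray            # (K,3) integer coordinates
    volume_ml: float
    suvmax: float
    suvpeak: float
    suvmean: float
    centroid_mm: tuple[float, float, float]
    equivocal: bool = False
    lds: int | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _suvpeak(pet: np.ndarray, voxels: np.ndarray, n_peak: int = 4) -> float:
    """Greedy hottest-connected-cluster peak: start at the hottest voxel
    and repeatedly add the hottest 26-neighbour inside the lesion until
    ``n_peak`` voxels are included; lesions smaller than that use all."""
    vals = pet[tuple(voxels.T)]
    if len(voxels) <= n_peak:
        return float(vals.mean())
    vset = {tuple(v): pet[tuple(v)] for v in voxels}
    start = tuple(voxels[int(np.argmax(vals))])
    cluster = {start}
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    while len(cluster) < n_peak:
        frontier = {}
        for c in cluster:
            for off in offsets:
                nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
                if nb in vset and nb not in cluster:
                    frontier[nb] = vset[nb]
        if not frontier:
            break
        cluster.add(max(frontier, key=frontier.get))
    return float(np.mean([vset[c] for c in cluster]))


def extract_components(mask: np.ndarray, pet: np.ndarray, spacing,
                       reference_lesions=None) -> list[LesionComponent]:
    """Connected components (26-connectivity) with per-component SUV stats.

    Components are ordered by descending volume, ties broken by
    lexicographic centroid, and relabelled 1..K in that order.  When
    ``reference_lesions`` metadata is given (for reference masks), the
    equivocal flag and LDS are carried over from the input label ids.
    """
    if mask.shape != pet.shape:
        raise ValueError(f"mask grid {mask.shape} != pet grid {pet.shape}")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    meta_by_label = {l.label: l for l in (reference_lesions or [])}

    comps = []
    fg = mask > 0
    labelled, n = ndimage.label(fg, structure=STRUCT_26)
    for lab in range(1, n + 1):
        vox = np.argwhere(labelled == lab)
        vals = pet[tuple(vox.T)]
        centroid = vox.mean(axis=0)
        centroid_mm = tuple(
            float((centroid[i] - (mask.shape[i] - 1) / 2.0) * spacing[i])
            for i in range(3))
        # carry over metadata from the dominant original label
        src_labels, counts = np.unique(mask[tuple(vox.T)], return_counts=True)
        src = int(src_labels[np.argmax(counts)])
        ref = meta_by_label.get(src)
        comps.append(LesionComponent(
            label=0, voxels=vox, volume_ml=len(vox) * voxel_ml,
            suvmax=float(vals.max()), suvpeak=_suvpeak(pet, vox),
            suvmean=float(vals.mean()), centroid_mm=centroid_mm,
            equivocal=bool(ref.equivocal) if ref else False,
            lds=ref.lds if ref else None))
    comps.sort(key=lambda c: (-c.volume_ml, c.centroid_mm))
    for i, c in enumerate(comps, start=1):
        c.label = i
    return comps


def binarize(prob: np.ndarray, threshold: float = 0.5,
             min_volume_ml: float = 0.0, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Threshold probabilities; optionally drop tiny components."""
    mask = prob > threshold
    if min_volume_ml > 0:
        voxel_ml = float(np.prod(spacing)) / 1000.0
        labelled, n = ndimage.label(mask, structure=STRUCT_26)
        for lab in range(1, n + 1):
            sel = labelled == lab
            if sel.sum() * voxel_ml < min_volume_ml:
                mask[sel] = False
    return mask.astype(np.uint8)


# ----------------------------------------------------------------------
# registration contracts
# ----------------------------------------------------------------------

def identity_transform(mask: np.ndarray, target_shape) -> np.ndarray:
    if tuple(mask.shape) != tuple(target_shape):
        raise RegistrationError(
            f"identity transform cannot map {mask.shape} to {target_shape}")
    return mask


def rigid_shift_transform(shift_voxels):
    """Transform factory: integer-voxel rigid shift, nearest neighbour."""
    shift = tuple(int(s) for s in shift_voxels)

    def apply(mask: np.ndarray, target_shape) -> np.ndarray:
        if tuple(mask.shape) != tuple(target_shape):
            raise RegistrationError("rigid shift requires equal grids")
        out = np.zeros_like(mask)
        src = [slice(max(-s, 0), mask.shape[i] - max(s, 0)) for i, s in enumerate(shift)]
        dst = [slice(max(s, 0), mask.shape[i] - max(-s, 0)) for i, s in enumerate(shift)]
        out[tuple(dst)] = mask[tuple(src)]
        return out

    return apply


def displacement_transform(field: np.ndarray):
    """Transform factory from a dense displacement field (voxel units)."""

    def apply(mask: np.ndarray, target_shape) -> np.ndarray:
        if field.shape[1:] != tuple(target_shape):
            raise RegistrationError(
                f"displacement field grid {field.shape[1:]} != {tuple(target_shape)}")
        idx = np.indices(mask.shape).astype(np.float32) + field
        return ndimage.map_coordinates(mask, idx, order=0, mode="constant", cval=0)

    return apply


def register_deformable(moving_pet: np.ndarray, fixed_pet: np.ndarray, spacing):
    """Demons deformable registration (SimpleITK backend); returns a
    transform usable by :func:`mpdr_filter`.

    Raises :class:`RegistrationError` if the backend is unavailable or
    the optimization fails — callers must not assume identity.
    """
    try:
        import SimpleITK as sitk
    except ImportError as e:  # pragma: no cover - depends on environment
        raise RegistrationError("SimpleITK not available for deformable registration") from e
    try:
        mov = sitk.GetImageFromArray(moving_pet.astype(np.float32))
        fix = sitk.GetImageFromArray(fixed_pet.astype(np.float32))
        for img in (mov, fix):
            img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(20)
        demons.SetStandardDeviations(2.0)
        disp = demons.Execute(fix, mov)
        arr = sitk.GetArrayFromImage(disp)  # (D,H,W,3), physical mm, xyz order
    except Exception as e:  # pragma: no cover
        raise RegistrationError(f"deformable registration failed: {e}") from e
    field = np.moveaxis(arr[..., ::-1], -1, 0)  # -> (3,D,H,W), index order
    for ax in range(3):
        field[ax] /= spacing[ax]
    return displacement_transform(field.astype(np.float32))


# ----------------------------------------------------------------------
# MPDR
# ----------------------------------------------------------------------

@dataclass
class MPDRAudit:
    kept: list = field(default_factory=list)      # (component label, overlap voxels)
    removed: list = field(default_factory=list)   # component labels


def mpdr_filter(pred_mask1: np.ndarray, pred_mask2: np.ndarray,
                transform=identity_transform) -> tuple[np.ndarray, MPDRAudit]:
    """Remove interim components with zero overlap against the propagated
    baseline mask.

    ``transform(mask, target_shape)`` maps the baseline mask onto the
    interim grid (nearest-neighbour semantics, binary in/out); identity
    and rigid shifts are provided for testing, and
    :func:`register_deformable` supplies a deformable backend.
    """
    propagated = transform(np.asarray(pred_mask1 > 0).astype(np.uint8),
                           pred_mask2.shape)
    if propagated.shape != pred_mask2.shape:
        raise RegistrationError("propagated mask grid mismatch")
    out = np.asarray(pred_mask2 > 0).astype(np.uint8)
    labelled, n = ndimage.label(out, structure=STRUCT_26)
    audit = MPDRAudit()
    for lab in range(1, n + 1):
        sel = labelled == lab
        overlap = int((propagated[sel] > 0).sum())
        if overlap == 0:
            out[sel] = 0
            audit.removed.append(lab)
        else:
            audit.kept.append((lab, overlap))
    return out, audit
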