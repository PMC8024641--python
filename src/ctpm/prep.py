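"""Image preparation: isotropic resampling, mask application, left/right lung
separation, crop-and-resize to the fixed network input grid, and the inverse
mapping back to the original grid.

Axis convention is (z, y, x) = (superior-inferior, anterior-posterior,
left-right); the long (128-voxel) network axis is superior-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, CONTINUOUS, LABEL, as_bool_mask

NETWORK_SHAPE = (128, 64, 64)

LEFT, RIGHT = "left", "right"
LEFT_LABEL, RIGHT_LABEL = 1, 2


@dataclass
class OriginalGrid:
    """Bookkeeping needed to re-embed a network-grid prediction into the
    pre-crop volume: full shape/spacing plus the crop bounding box."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    bbox_start: tuple[int, int, int]
    bbox_shape: tuple[int, int, int]


@dataclass
class LungSample:
    """One single-lung training/testing unit on the network grid."""

    ct: ImageVolume
    perfusion: ImageVolume
    roi_mask: ImageVolume
    side: str
    subject_id: str
    original_grid: Optional[OriginalGrid] = None
    # original-grid references kept for overall (recovered-grid) evaluation
    perfusion_original: Optional[ImageVolume] = None
    roi_mask_original: Optional[ImageVolume] = None
    provenance: dict = field(default_factory=dict)

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.side}"


# --------------------------------------------------------------------------
def resample_isotropic(
    vol: ImageVolume, target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> ImageVolume:
    """Resample to the target spacing (trilinear for continuous volumes,
    nearest-neighbour for label volumes), preserving physical extent."""
    if any(s <= 0 for s in target_spacing_mm) or len(target_spacing_mm) != 3:
        raise ValueError(f"target spacing must be 3 positive reals: {target_spacing_mm}")
    if any(d == 0 for d in vol.shape):
        raise ValueError("cannot resample a zero-extent volume")
    factors = [s / t for s, t in zip(vol.spacing_mm, target_spacing_mm)]
    new_shape = [max(1, int(round(d * f))) for d, f in zip(vol.shape, factors)]
    order = 0 if vol.interpolation_class == LABEL else 1
    zoom = [n / d for n, d in zip(new_shape, vol.shape)]
    out = ndimage.zoom(
        np.asarray(vol.values, dtype=np.float32 if order else vol.values.dtype),
        zoom,
        order=order,
        grid_mode=True,
        mode="nearest",
    )
    out = out[: new_shape[0], : new_shape[1], : new_shape[2]]
    if vol.interpolation_class == LABEL:
        out = np.round(out).astype(np.int16)
    return ImageVolume(
        out, tuple(target_spacing_mm), vol.origin_mm, vol.interpolation_class
    )


def apply_mask(vol: ImageVolume, mask: ImageVolume | np.ndarray, fill: float = 0.0) -> ImageVolume:
    """Zero (or ``fill``) everything outside the mask; in-mask voxels pass
    through unchanged."""
    m = as_bool_mask(mask)
    if m.shape != vol.shape:
        raise ValueError(f"mask shape {m.shape} != volume shape {vol.shape}")
    out = np.asarray(vol.values).copy()
    out[~m] = fill
    return vol.with_values(out)


def _component_split(mask_vals: np.ndarray) -> np.ndarray:
    """Fallback left/right labelling for an unlabelled binary mask: connected
    components, side assigned by centroid along the left-right (x) axis.
    Smaller x-centroid -> left. Extra small components are merged into the
    nearer of the two largest. Ties broken toward larger component = right."""
    labelled, n = ndimage.label(mask_vals > 0)
    if n < 2:
        raise ValueError(
            "cannot separate lungs: unlabelled mask has a single connected component"
        )
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    big = [int(order[0]) + 1, int(order[1]) + 1]
    centroids = ndimage.center_of_mass(mask_vals > 0, labelled, index=big)
    cx = [c[2] for c in centroids]
    if cx[0] == cx[1]:  # degenerate tie: larger component is the right lung
        left_lab, right_lab = big[1], big[0]
    elif cx[0] < cx[1]:
        left_lab, right_lab = big[0], big[1]
    else:
        left_lab, right_lab = big[1], big[0]
    left_cx = cx[0] if left_lab == big[0] else cx[1]
    right_cx = cx[1] if left_lab == big[0] else cx[0]
    out = np.zeros_like(labelled, dtype=np.int16)
    out[labelled == left_lab] = LEFT_LABEL
    out[labelled == right_lab] = RIGHT_LABEL
    # merge any residual components into the nearer large lung (x distance)
    for lab in range(1, n + 1):
        if lab in (left_lab, right_lab):
            continue
        c = ndimage.center_of_mass(mask_vals > 0, labelled, index=lab)
        target = LEFT_LABEL if abs(c[2] - left_cx) <= abs(c[2] - right_cx) else RIGHT_LABEL
        out[labelled == lab] = target
    return out


def separate_lungs(
    ct: ImageVolume,
    perfusion: ImageVolume,
    mask: ImageVolume,
) -> dict[str, dict]:
    """Split a subject into independent left / right single-lung volume sets.

    The mask may carry explicit labels (1=left, 2=right); an unlabelled binary
    mask is split by connected components.  Returns
    ``{"left": {...}, "right": {...}}`` with per-side binary masks and the
    untouched (still full-grid) CT / perfusion volumes.
    """
    vals = np.asarray(mask.values)
    labels = set(np.unique(vals)) - {0}
    if labels <= {1} or labels <= {LEFT_LABEL, RIGHT_LABEL} and len(labels) < 2:
        vals = _component_split(vals)
    elif not labels <= {LEFT_LABEL, RIGHT_LABEL}:
        raise ValueError(f"unexpected mask labels {sorted(labels)}")
    out = {}
    for side, lab in ((LEFT, LEFT_LABEL), (RIGHT, RIGHT_LABEL)):
        side_mask = (vals == lab).astype(np.int16)
        if side_mask.sum() == 0:
            raise ValueError(f"empty {side} lung in mask")
        out[side] = {
            "ct": ct,
            "perfusion": perfusion,
            "mask": ImageVolume(side_mask, mask.spacing_mm, mask.origin_mm, LABEL),
        }
    return out


def _bbox(mask_vals: np.ndarray) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    idx = np.argwhere(mask_vals > 0)
    if idx.size == 0:
        raise ValueError("empty mask: no bounding box")
    start = idx.min(axis=0)
    stop = idx.max(axis=0) + 1
    return tuple(int(v) for v in start), tuple(int(v) for v in (stop - start))


def _resize(vals: np.ndarray, target_shape, order: int) -> np.ndarray:
    if vals.shape == tuple(target_shape):
        return vals.astype(np.float32) if order else vals
    zoom = [t / s for t, s in zip(target_shape, vals.shape)]
    out = ndimage.zoom(
        np.asarray(vals, dtype=np.float32),
        zoom,
        order=order,
        grid_mode=True,
        mode="nearest",
    )
    return out[: target_shape[0], : target_shape[1], : target_shape[2]]


def crop_and_resize(
    ct: ImageVolume,
    perfusion: ImageVolume,
    mask: ImageVolume,
    side: str,
    subject_id: str,
    target_shape: tuple[int, int, int] = NETWORK_SHAPE,
) -> LungSample:
    """Crop to the tight bounding box of the (single-lung) mask and resize to
    the network input shape.  Continuous volumes are trilinear, the mask is
    nearest-neighbour.  The pre-crop grid and bounding box are recorded for
    :func:`recover_original_grid`."""
    mvals = np.asarray(mask.values)
    if ct.shape != mvals.shape or perfusion.shape != mvals.shape:
        raise ValueError("ct / perfusion / mask shapes differ")
    start, bshape = _bbox(mvals)
    sl = tuple(slice(s, s + b) for s, b in zip(start, bshape))
    ct_c = _resize(np.asarray(ct.values)[sl], target_shape, order=1)
    pf_c = _resize(np.asarray(perfusion.values)[sl], target_shape, order=1)
    mk_c = _resize(mvals[sl], target_shape, order=0).astype(np.int16)
    if mk_c.sum() == 0:  # nearest-neighbour cannot drop everything from a tight bbox
        raise ValueError("mask lost under resize")
    grid = OriginalGrid(
        shape=tuple(int(v) for v in mvals.shape),
        spacing_mm=mask.spacing_mm,
        bbox_start=start,
        bbox_shape=bshape,
    )
    spacing = tuple(
        b * s / t for b, s, t in zip(bshape, mask.spacing_mm, target_shape)
    )
    return LungSample(
        ct=ImageVolume(ct_c, spacing, interpolation_class=CONTINUOUS),
        perfusion=ImageVolume(pf_c, spacing, interpolation_class=CONTINUOUS),
        roi_mask=ImageVolume(mk_c, spacing, interpolation_class=LABEL),
        side=side,
        subject_id=subject_id,
        original_grid=grid,
        perfusion_original=apply_mask(perfusion, mask),
        roi_mask_original=mask,
    )


def recover_original_grid(pred: ImageVolume, sample: LungSample) -> ImageVolume:
    """Inverse of :func:`crop_and_resize`: resize a network-grid prediction
    back to the recorded bounding box and re-embed it (zero outside) into the
    original grid."""
    grid = sample.original_grid
    if grid is None:
        raise ValueError("sample has no original_grid metadata")
    back = _resize(np.asarray(pred.values), grid.bbox_shape, order=1)
    out = np.zeros(grid.shape, dtype=np.float32)
    sl = tuple(slice(s, s + b) for s, b in zip(grid.bbox_start, grid.bbox_shape))
    out[sl] = back
    return ImageVolume(out, grid.spacing_mm, interpolation_class=CONTINUOUS)


def prepare_subject(
    ct: ImageVolume,
    perfusion: ImageVolume,
    mask: ImageVolume,
    subject_id: str,
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_shape: tuple[int, int, int] = NETWORK_SHAPE,
) -> list[LungSample]:
    """Full preparation chain for one subject: isotropic resample, mask
    application, lung separation, per-lung crop/resize.  Returns the left and
    right :class:`LungSample` (raw intensities; processing comes next)."""
    ct_r = resample_isotropic(ct, target_spacing_mm)
    pf_r = resample_isotropic(perfusion, target_spacing_mm)
    mk_r = resample_isotropic(mask, target_spacing_mm)
    samples = []
    for side, vols in separate_lungs(ct_r, pf_r, mk_r).items():
        ct_m = apply_mask(vols["ct"], vols["mask"], fill=0.0)
        pf_m = apply_mask(vols["perfusion"], vols["mask"], fill=0.0)
        samples.append(
            crop_and_resize(ct_m, pf_m, vols["mask"], side, subject_id, target_shape)
        )
    return samples
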