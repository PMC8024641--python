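"""Image processing: SPECT normalization + uniform discretization, and CT
enhancement (windowed cumulative-histogram equalization followed by a median
and a uniform filter).  Every step is independently toggleable so that
ablation experiments can remove it.

Conventions
-----------
* The normalization divisor (the "high-intensity region" value, HIR) is the
  75th percentile of in-mask perfusion, with the linear-interpolation
  percentile definition.
* The cumulative histogram for CT equalization is computed over in-mask
  voxels only, after clipping to the HU window [-1000, -300]; a voxel maps to
  ``#{in-mask values <= v} / N`` so the equalized output lies in (0, 1] and a
  constant volume maps to exactly 1.0.
* Filters are mask-aware by default: window statistics are taken over in-mask
  neighbours only, so background zeros never darken the pleural boundary.
  The median kernel is an even 10-voxel edge; the window uses floor-centred
  offsets (-5..+4 per axis).  The uniform (mean) kernel is 5 voxels, centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit, prange

from .volume import ImageVolume, as_bool_mask
from .prep import LungSample


@dataclass
class ProcessingConfig:
    hir_percentile: float = 75.0
    n_levels: int = 11
    hu_window: tuple[float, float] = (-1000.0, -300.0)
    median_kernel_vox: int = 10
    uniform_kernel_vox: int = 5
    discretize: bool = True
    contrast_enhance: bool = True
    median_filter: bool = True
    uniform_filter: bool = True
    mask_aware_filters: bool = True
    hir_in_mask_only: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"hu_window low must be < high, got {self.hu_window}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.median_kernel_vox < 1 or self.uniform_kernel_vox < 1:
            raise ValueError("filter kernels must be >= 1 voxel")
        if not 0 < self.hir_percentile <= 100:
            raise ValueError("hir_percentile must lie in (0, 100]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hu_window"] = list(self.hu_window)
        return d


# ------------------------------------------------------------------ SPECT
def normalize_spect(
    perf: ImageVolume, mask: ImageVolume | np.ndarray, cfg: ProcessingConfig | None = None
) -> ImageVolume:
    """Divide in-mask perfusion by the HIR (75th-percentile) value; zero
    outside the mask."""
    cfg = cfg or ProcessingConfig()
    m = as_bool_mask(mask)
    vals = np.asarray(perf.values, dtype=np.float64)
    if m.shape != vals.shape:
        raise ValueError("mask / perfusion shape mismatch")
    if not m.any():
        raise ValueError("empty mask")
    pool = vals[m] if cfg.hir_in_mask_only else vals
    if not (pool > 0).any():
        raise ValueError("no positive perfusion values: cannot normalize")
    hir = float(np.percentile(pool, cfg.hir_percentile))
    if hir <= 0:
        raise ValueError(f"degenerate perfusion: HIR={hir}")
    out = np.zeros_like(vals, dtype=np.float32)
    out[m] = (vals[m] / hir).astype(np.float32)
    return perf.with_values(out)


def discretize(
    norm: ImageVolume, mask: ImageVolume | np.ndarray, cfg: ProcessingConfig | None = None
) -> ImageVolume:
    """Clip normalized perfusion to [0, 1] and snap to the nearest of
    ``n_levels`` uniform levels {0, 1/(n-1), ..., 1}; ties round up."""
    cfg = cfg or ProcessingConfig()
    m = as_bool_mask(mask)
    vals = np.asarray(norm.values, dtype=np.float64)
    n = cfg.n_levels
    clipped = np.clip(vals, 0.0, 1.0)
    # floor(x*(n-1)+0.5) rounds exact midpoints toward the higher level
    levels = np.floor(clipped * (n - 1) + 0.5) / (n - 1)
    out = np.zeros_like(vals, dtype=np.float32)
    out[m] = levels[m].astype(np.float32)
    return norm.with_values(out)


# --------------------------------------------------------------------- CT
def _equalize(vals_in: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Cumulative-histogram equalization of the in-mask value vector
    (already clipped to [lo, hi]); output in (0, 1]."""
    srt = np.sort(vals_in)
    n = srt.size
    # chf_low: cumulative count strictly below the window low bound (0 after
    # clipping); chf_high: inclusive count at the high bound (= n)
    chf_low = int(np.searchsorted(srt, lo, side="left"))
    chf_high = int(np.searchsorted(srt, hi, side="right"))
    denom = chf_high - chf_low
    ranks = np.searchsorted(srt, vals_in, side="right")
    if denom <= 0:  # all values pinned at the low bound
        return np.ones_like(vals_in, dtype=np.float64)
    return (ranks - chf_low) / denom


@njit(parallel=True, cache=False)
def _masked_median_3d(vals, mask, out, off_lo, off_hi):  # pragma: no cover - numba
    nz, ny, nx = vals.shape
    k = off_hi - off_lo
    for z in prange(nz):
        buf = np.empty(k * k * k, dtype=np.float64)
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    out[z, y, x] = 0.0
                    continue
                cnt = 0
                for dz in range(off_lo, off_hi):
                    zz = z + dz
                    if zz < 0 or zz >= nz:
                        continue
                    for dy in range(off_lo, off_hi):
                        yy = y + dy
                        if yy < 0 or yy >= ny:
                            continue
                        for dx in range(off_lo, off_hi):
                            xx = x + dx
                            if xx < 0 or xx >= nx:
                                continue
                            if mask[zz, yy, xx]:
                                buf[cnt] = vals[zz, yy, xx]
                                cnt += 1
                out[z, y, x] = np.median(buf[:cnt])


def masked_median_filter(vals: np.ndarray, mask: np.ndarray, kernel: int) -> np.ndarray:
    """Median over in-mask neighbours in a ``kernel``-edge cube.  Even kernels
    use floor-centred offsets (-k//2 .. k//2 - 1)."""
    off_lo = -(kernel // 2)
    off_hi = kernel + off_lo
    out = np.zeros_like(vals, dtype=np.float64)
    _masked_median_3d(
        np.ascontiguousarray(vals, dtype=np.float64),
        np.ascontiguousarray(mask.astype(np.bool_)),
        out,
        off_lo,
        off_hi,
    )
    return out


def masked_uniform_filter(vals: np.ndarray, mask: np.ndarray, kernel: int) -> np.ndarray:
    """Mean over in-mask neighbours in a ``kernel``-edge cube (normalized box
    filter); zero outside the mask."""
    from scipy import ndimage

    origin = 0 if kernel % 2 == 1 else -1  # floor-centring for even kernels
    m = mask.astype(np.float64)
    num = ndimage.uniform_filter(vals * m, size=kernel, mode="constant", origin=origin)
    den = ndimage.uniform_filter(m, size=kernel, mode="constant", origin=origin)
    out = np.zeros_like(vals, dtype=np.float64)
    inm = mask & (den > 0)
    out[inm] = num[inm] / den[inm]
    return out


def enhance_ct(
    ct: ImageVolume, mask: ImageVolume | np.ndarray, cfg: ProcessingConfig | None = None
) -> ImageVolume:
    """CT enhancement: clip to the HU window, cumulative-histogram equalize
    over in-mask voxels, then (optionally) median- and mean-filter.  Order is
    fixed: equalize -> median -> uniform.  Out-of-mask voxels are zero."""
    cfg = cfg or ProcessingConfig()
    m = as_bool_mask(mask)
    vals = np.asarray(ct.values, dtype=np.float64)
    if m.shape != vals.shape:
        raise ValueError("mask / CT shape mismatch")
    if not m.any():
        raise ValueError("empty mask")
    lo, hi = cfg.hu_window
    clipped = np.clip(vals, lo, hi)
    out = np.zeros_like(vals)
    if cfg.contrast_enhance:
        out[m] = _equalize(clipped[m], lo, hi)
    else:
        out[m] = clipped[m]
    if cfg.median_filter:
        if cfg.mask_aware_filters:
            out = masked_median_filter(out, m, cfg.median_kernel_vox)
        else:
            from scipy import ndimage

            origin = 0 if cfg.median_kernel_vox % 2 == 1 else -1
            out = ndimage.median_filter(
                out, size=cfg.median_kernel_vox, mode="constant", origin=origin
            )
            out[~m] = 0.0
    if cfg.uniform_filter:
        if cfg.mask_aware_filters:
            out = masked_uniform_filter(out, m, cfg.uniform_kernel_vox)
        else:
            from scipy import ndimage

            out = ndimage.uniform_filter(out, size=cfg.uniform_kernel_vox, mode="constant")
            out[~m] = 0.0
    return ct.with_values(out.astype(np.float32))


# ----------------------------------------------------------------- sample
def process_sample(sample: LungSample, cfg: ProcessingConfig | None = None) -> LungSample:
    """Apply CT enhancement and SPECT normalization(+discretization) to a
    prepared :class:`LungSample`, honouring the ablation toggles.  The raw
    perfusion channel is replaced by the [0, 1] training label."""
    cfg = cfg or ProcessingConfig()
    m = sample.roi_mask
    ct = enhance_ct(sample.ct, m, cfg)
    label = normalize_spect(sample.perfusion, m, cfg)
    if cfg.discretize:
        label = discretize(label, m, cfg)
    perf_orig = sample.perfusion_original
    mask_orig = sample.roi_mask_original
    if perf_orig is not None and mask_orig is not None:
        perf_orig = normalize_spect(perf_orig, mask_orig, cfg)
    return LungSample(
        ct=ct,
        perfusion=label,
        roi_mask=m,
        side=sample.side,
        subject_id=sample.subject_id,
        original_grid=sample.original_grid,
        perfusion_original=perf_orig,
        roi_mask_original=mask_orig,
        provenance=dict(sample.provenance, processing=cfg.to_dict()),
    )
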