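"""Digital lung phantoms: paired CT / perfusion cohorts with known ground truth.

The clinical cohorts this framework targets (SPECT/CT perfusion scans) cannot
be redistributed, so every test and example runs on synthetic subjects that
reproduce the *structure* the method relies on:

* two ellipsoidal lung fields labelled left/right, with a trachea-like tube
  carved out of the parenchyma mask;
* a perfusion field with a gravity-dependent gradient and log-normal count
  speckle, generated on a coarse (SPECT-like) grid and trilinearly upsampled;
* low-functional defect regions of two archetypes — "sharp" (step boundary)
  and "gradient" (linear ramp over 10 mm) — occupying a controlled fraction of
  the parenchyma;
* CT texture informatively coupled to the underlying perfusion: in-mask HU is
  a monotone (deliberately nonlinear, CDF-compressing) function of the local
  perfusion level, blended with an independent texture field according to
  ``coupling_strength``.  At ``coupling_strength=0`` the CT carries no
  functional information at all.

Generation is a pure function of :class:`PhantomSpec`: per-subject RNG streams
are keyed by ``(seed, 0, subject_index)`` and the cohort split by
``(seed, 1, 0)``, so any subject is reproducible independently of cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, CONTINUOUS, LABEL

DEFECT_TYPES = ("sharp", "gradient", "none")

# fraction of subjects in the training split (31 of 42 in the study design
# this generator emulates)
TRAIN_FRACTION = 31.0 / 42.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic cohort.

    ``coupling_strength`` in [0, 1] sets how strongly in-mask CT intensity
    encodes the (noise-free) perfusion level; ``noise_sd`` is the relative SD
    of multiplicative perfusion noise (the same scalar also drives additive CT
    noise with SD ``100 * noise_sd`` HU).
    """

    n_subjects: int = 42
    seed: int = 0
    grid_shape: tuple[int, int, int] = (160, 96, 96)
    ct_spacing_mm: tuple[float, float, float] = (1.25, 0.977, 0.977)
    defect_type_mix: dict = field(
        default_factory=lambda: {"sharp": 0.4, "gradient": 0.4, "none": 0.2}
    )
    defect_fraction_range: tuple[float, float] = (0.10, 0.40)
    coupling_strength: float = 0.9
    noise_sd: float = 0.05
    perfusion_spacing_mm: float = 4.0

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid dimensions must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.ct_spacing_mm):
            raise ValueError("ct_spacing_mm must be positive")
        total = sum(self.defect_type_mix.get(t, 0.0) for t in DEFECT_TYPES)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"defect_type_mix must sum to 1, got {total}")
        lo, hi = self.defect_fraction_range
        if not (0.0 < lo <= hi < 0.6):
            raise ValueError(
                f"defect_fraction_range must satisfy 0 < lo <= hi < 0.6, got {lo, hi}"
            )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PhantomSubject:
    """One synthetic subject: CT (HU), perfusion (counts), labelled mask,
    and the binary low-functional ground truth."""

    subject_id: str
    ct: ImageVolume
    perfusion: ImageVolume
    mask: ImageVolume  # 0 background, 1 left lung, 2 right lung
    defect_truth: ImageVolume
    defect_type: str = "none"
    defect_fraction: float = 0.0


def _subject_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), 0, int(subject_index)])


def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Empirical CDF transform onto (0, 1] (average ranks not needed: values
    are continuous draws)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=np.float64)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks / values.size


def _coarse_field(rng, fine_shape, fine_spacing, coarse_mm, log_sd, gradient_amp):
    """Gravity-like gradient with multiplicative log-normal speckle, generated
    at SPECT-like resolution and trilinearly upsampled to the CT grid."""
    extent = np.array(fine_shape) * np.array(fine_spacing)
    coarse_shape = np.maximum(2, np.round(extent / coarse_mm)).astype(int)
    zz, yy, xx = np.meshgrid(*[np.linspace(0, 1, s) for s in coarse_shape], indexing="ij")
    base = 1.0 + gradient_amp * yy  # dependent (posterior) lung is better perfused
    speckle = np.exp(rng.normal(0.0, log_sd, size=tuple(coarse_shape)))
    coarse = base * speckle
    zoom = np.array(fine_shape) / coarse_shape
    fine = ndimage.zoom(coarse, zoom, order=1, grid_mode=True, mode="nearest")
    return fine[: fine_shape[0], : fine_shape[1], : fine_shape[2]]


def generate_subject(spec: PhantomSpec, subject_index: int) -> PhantomSubject:
    """Generate one subject. Deterministic in ``(spec, subject_index)``."""
    if subject_index >= spec.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} out of range for n_subjects={spec.n_subjects}"
        )
    rng = _subject_rng(spec, subject_index)
    shape = tuple(int(g) for g in spec.grid_shape)
    spacing = spec.ct_spacing_mm
    extent = np.array(shape) * np.array(spacing)

    coords = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij", sparse=True
    )
    zz, yy, xx = coords

    # --- lung geometry: two ellipsoids, randomized semi-axes and centres ----
    mask = np.zeros(shape, dtype=np.int16)
    for label, x_frac in ((1, 0.30), (2, 0.70)):  # 1 = left (smaller x), 2 = right
        semi = np.array([0.40, 0.28, 0.17]) * extent
        semi *= 1.0 + rng.uniform(-0.15, 0.15, size=3)
        centre = np.array([0.5, 0.5, x_frac]) * extent
        centre += rng.uniform(-0.02, 0.02, size=3) * extent
        ell = (
            ((zz - centre[0]) / semi[0]) ** 2
            + ((yy - centre[1]) / semi[1]) ** 2
            + ((xx - centre[2]) / semi[2]) ** 2
        ) <= 1.0
        mask[ell] = label

    # trachea-like tube: carved out of the parenchyma mask
    t_r = 0.055 * extent[2]
    tube = (
        (((yy - 0.45 * extent[1]) / t_r) ** 2 + ((xx - 0.5 * extent[2]) / t_r) ** 2) <= 1.0
    ) & (zz <= 0.55 * extent[0])
    tube = np.broadcast_to(tube, shape)
    mask[tube] = 0
    inmask = mask > 0
    n_mask = int(inmask.sum())
    if n_mask == 0:
        raise ValueError("degenerate phantom: empty lung mask (grid too small?)")

    # --- defect ground truth ------------------------------------------------
    defect_type = str(
        rng.choice(
            np.array(DEFECT_TYPES, dtype=object),
            p=[spec.defect_type_mix.get(t, 0.0) for t in DEFECT_TYPES],
        )
    )
    lo, hi = spec.defect_fraction_range
    frac = float(rng.uniform(lo, hi))
    deficit = np.zeros(shape, dtype=np.float64)  # perfusion reduction in [0,1)
    defect = np.zeros(shape, dtype=bool)
    if defect_type != "none":
        side = int(rng.integers(1, 3))
        side_idx = np.argwhere(mask == side)
        centre_vox = side_idx[int(rng.integers(len(side_idx)))]
        centre_mm = centre_vox * np.array(spacing)
        scales = rng.uniform(0.7, 1.4, size=3)
        d = np.sqrt(
            ((zz - centre_mm[0]) / scales[0]) ** 2
            + ((yy - centre_mm[1]) / scales[1]) ** 2
            + ((xx - centre_mm[2]) / scales[2]) ** 2
        )
        d = np.broadcast_to(d, shape)
        d_in = d[inmask]
        k = int(round(frac * n_mask))
        k = min(max(k, 1), n_mask)
        # exact-count selection: stable sort breaks distance ties (the
        # ellipsoid is reflection-symmetric about integer centres)
        order = np.argsort(d_in, kind="stable")
        thr = float(d_in[order[k - 1]])
        sel = np.zeros(n_mask, dtype=bool)
        sel[order[:k]] = True
        defect = np.zeros(shape, dtype=bool)
        defect[inmask] = sel
        depth = float(rng.uniform(0.5, 0.85))
        if defect_type == "sharp":
            deficit[defect] = depth
        else:  # linear ramp over 10 mm from the boundary toward the core
            ramp_mm = 10.0
            deficit[defect] = depth * np.minimum(1.0, (thr - d[defect]) / ramp_mm)

    # --- perfusion ----------------------------------------------------------
    gravity = _coarse_field(
        rng, shape, spacing, spec.perfusion_spacing_mm, log_sd=0.2, gradient_amp=0.8
    )
    perf_clean = gravity * (1.0 - deficit)
    perf = perf_clean * (1.0 + rng.normal(0.0, spec.noise_sd, size=shape))
    perf = np.clip(perf, 0.0, None) * 100.0
    perf[~inmask] = 0.0

    # --- CT -----------------------------------------------------------------
    # q: perfusion quantile of the noise-free field within the parenchyma;
    # the CDF-compressing q**2 leaves low-functional tissue in a narrow dark
    # HU band, which is exactly what cumulative-histogram enhancement undoes.
    ct = np.full(shape, 40.0, dtype=np.float64)  # soft-tissue background
    q = np.zeros(shape)
    q[inmask] = _rank_unit(perf_clean[inmask])
    texture = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.5)
    t_unit = np.zeros(shape)
    t_unit[inmask] = _rank_unit(texture[inmask])
    c = spec.coupling_strength
    mix = np.clip(c * q**2 + (1.0 - c) * t_unit, 0.0, 1.0)
    ct_lung = -950.0 + 600.0 * mix
    if spec.noise_sd > 0:
        ct_lung = ct_lung + rng.normal(0.0, 100.0 * spec.noise_sd, size=shape)
    ct[inmask] = np.clip(ct_lung[inmask], -1000.0, -300.0)
    ct[tube & ~inmask] = -300.0  # trachea lumen (background stays >= -300 HU)

    sid = f"phantom{subject_index:03d}"
    return PhantomSubject(
        subject_id=sid,
        ct=ImageVolume(ct.astype(np.float32), spacing, interpolation_class=CONTINUOUS),
        perfusion=ImageVolume(perf.astype(np.float32), spacing, interpolation_class=CONTINUOUS),
        mask=ImageVolume(mask, spacing, interpolation_class=LABEL),
        defect_truth=ImageVolume(defect.astype(np.int16), spacing, interpolation_class=LABEL),
        defect_type=defect_type,
        defect_fraction=frac,
    )


def split_manifest(spec: PhantomSpec) -> dict:
    """Deterministic train/test split with the 31:42 training proportion."""
    n = int(spec.n_subjects)
    if n < 2:
        raise ValueError(f"need at least 2 subjects to split, got {n}")
    n_train = int(round(n * TRAIN_FRACTION))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1, 0])
    perm = rng.permutation(n)
    train = sorted(int(i) for i in perm[:n_train])
    test = sorted(int(i) for i in perm[n_train:])
    ids = [f"phantom{i:03d}" for i in range(n)]
    return {
        "seed": int(spec.seed),
        "n_subjects": n,
        "train": [ids[i] for i in train],
        "test": [ids[i] for i in test],
        "train_indices": train,
        "test_indices": test,
    }


def generate_cohort(spec: PhantomSpec) -> tuple[list[PhantomSubject], dict]:
    """All subjects plus the split manifest (pure function of the spec)."""
    manifest = split_manifest(spec)  # validates n_subjects >= 2 first
    subjects = [generate_subject(spec, i) for i in range(spec.n_subjects)]
    return subjects, manifest


def save_cohort(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write the cohort as NIfTI files plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, manifest = generate_cohort(spec)
    for s in subjects:
        s.ct.save(out / f"{s.subject_id}_ct.nii.gz")
        s.perfusion.save(out / f"{s.subject_id}_perf.nii.gz")
        s.mask.save(out / f"{s.subject_id}_mask.nii.gz")
        s.defect_truth.save(out / f"{s.subject_id}_defect.nii.gz")
    manifest = dict(manifest, phantom_spec=spec_to_dict(spec))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["ct_spacing_mm"] = list(spec.ct_spacing_mm)
    d["defect_fraction_range"] = list(spec.defect_fraction_range)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key in ("grid_shape", "ct_spacing_mm", "defect_fraction_range"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)
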