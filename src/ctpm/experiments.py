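"""Ablation-study harness: declaratively runs the image-processing ablation
suite and the architecture grid on a phantom cohort and emits comparison
tables (R, SSIM, SSIM+R, percent difference vs. the base row).

Every row is regenerable from its stored manifest alone (resolved config +
seed + cohort content hash).  Suites default to phantom-scale settings
(reduced grids and epochs) so a full suite runs on one CPU; ``full_scale``
restores the 128x64x64 / 500-epoch configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsConfig, evaluate_cohort, percent_difference
from .model import ModelConfig
from .phantom import PhantomSpec, generate_subject, split_manifest, spec_to_dict, spec_from_dict
from .prep import prepare_subject, LungSample
from .processing import ProcessingConfig, process_sample
from .training import PerfusionMapper, TrainConfig


# ---------------------------------------------------------------- configs
@dataclass
class RunConfig:
    """Fully resolved configuration of one training+evaluation run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    target_shape: tuple[int, int, int] = (128, 64, 64)
    resample_spacing: tuple[float, float, float] | None = (1.0, 1.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "phantom": spec_to_dict(self.phantom),
            "processing": self.processing.to_dict(),
            "model": self.model.to_dict(),
            "training": self.training.to_dict(),
            "metrics": self.metrics.to_dict(),
            "target_shape": list(self.target_shape),
            "resample_spacing": list(self.resample_spacing)
            if self.resample_spacing is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            phantom=spec_from_dict(d["phantom"]),
            processing=ProcessingConfig(**{k: tuple(v) if k == "hu_window" else v
                                           for k, v in d["processing"].items()}),
            model=ModelConfig.from_dict(d["model"]),
            training=TrainConfig(**d["training"]),
            metrics=MetricsConfig(**d["metrics"]),
            target_shape=tuple(d["target_shape"]),
            resample_spacing=tuple(d["resample_spacing"])
            if d.get("resample_spacing") is not None
            else None,
        )


def apply_override(cfg_dict: dict, path: str, value) -> None:
    """Set a nested config key addressed as e.g. 'model.kernel_size'."""
    keys = path.split(".")
    node = cfg_dict
    for k in keys[:-1]:
        if k not in node:
            raise KeyError(f"override path {path!r}: no key {k!r}")
        node = node[k]
    if keys[-1] not in node:
        raise KeyError(f"override path {path!r}: no key {keys[-1]!r}")
    node[keys[-1]] = value


@dataclass
class AblationSpec:
    name: str
    base_config: dict
    overrides: list[tuple[str, object]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0])

    def resolved(self) -> RunConfig:
        cfg = copy.deepcopy(self.base_config)
        for path, value in self.overrides:
            apply_override(cfg, path, value)
        return RunConfig.from_dict(cfg)


# ---------------------------------------------------------------- presets
def small_run_config(
    n_subjects: int = 8,
    seed: int = 0,
    epochs: int = 40,
    grid_shape=(48, 32, 32),
    target_shape=(32, 16, 16),
    kernel_size: int = 3,
) -> RunConfig:
    """Desk-scale defaults: reduced phantom grids, a narrow 2-level network,
    and a few dozen epochs, so a whole ablation suite runs on one CPU."""
    return RunConfig(
        phantom=PhantomSpec(
            n_subjects=n_subjects,
            seed=seed,
            grid_shape=tuple(grid_shape),
            ct_spacing_mm=(1.0, 1.0, 1.0),
        ),
        processing=ProcessingConfig(median_kernel_vox=4, uniform_kernel_vox=3),
        model=ModelConfig(
            width_multiplier=3,
            kernel_size=kernel_size,
            n_residual_blocks=2,
            n_stride_convs=2,
        ),
        training=TrainConfig(max_epochs=epochs, seed=seed, batch_size=2),
        target_shape=tuple(target_shape),
        resample_spacing=None,
    )


def full_scale_config(seed: int = 0) -> RunConfig:
    """The full-resolution configuration (128x64x64 inputs, width 4x32,
    kernel 5, 8 residual blocks, 500-epoch cap)."""
    return RunConfig(
        phantom=PhantomSpec(seed=seed),
        training=TrainConfig(seed=seed),
    )


# --------------------------------------------------------------- pipeline
def cohort_hash(phantom_spec: PhantomSpec, manifest: dict) -> str:
    payload = json.dumps(
        {"spec": spec_to_dict(phantom_spec),
         "train": manifest["train"], "test": manifest["test"]},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def prepare_cohort(cfg: RunConfig) -> tuple[list[LungSample], list[LungSample], dict]:
    """Generate the phantom cohort and run image preparation; returns raw
    (unprocessed) train and test lung samples plus the split manifest."""
    manifest = split_manifest(cfg.phantom)
    out = {"train": [], "test": []}
    for group in ("train", "test"):
        for idx in manifest[f"{group}_indices"]:
            subj = generate_subject(cfg.phantom, idx)
            if cfg.resample_spacing is not None:
                samples = prepare_subject(
                    subj.ct, subj.perfusion, subj.mask, subj.subject_id,
                    target_spacing_mm=cfg.resample_spacing,
                    target_shape=cfg.target_shape,
                )
            else:
                from .prep import separate_lungs, apply_mask, crop_and_resize

                samples = []
                for side, vols in separate_lungs(subj.ct, subj.perfusion, subj.mask).items():
                    ct_m = apply_mask(vols["ct"], vols["mask"])
                    pf_m = apply_mask(vols["perfusion"], vols["mask"])
                    samples.append(
                        crop_and_resize(ct_m, pf_m, vols["mask"], side,
                                        subj.subject_id, cfg.target_shape)
                    )
            out[group].extend(samples)
    return out["train"], out["test"], manifest


def run_pipeline(cfg: RunConfig, seed: int | None = None,
                 prepared: tuple | None = None) -> dict:
    """One end-to-end run: phantom -> prep -> processing -> train -> evaluate
    held-out lungs.  Returns metrics plus a manifest sufficient to regenerate
    the run."""
    if seed is not None:
        cfg = copy.deepcopy(cfg)
        cfg.training.seed = seed
    train_raw, test_raw, manifest = prepared if prepared is not None else prepare_cohort(cfg)
    train_s = [process_sample(s, cfg.processing) for s in train_raw]
    test_s = [process_sample(s, cfg.processing) for s in test_raw]
    mapper = PerfusionMapper(cfg.model, cfg.training).fit(train_s)
    preds = [mapper.predict(s) for s in test_s]
    report = evaluate_cohort(preds, test_s, cfg.metrics)
    return {
        "summary": report.summary,
        "per_sample": report.per_sample.to_dict(orient="records"),
        "n_train": len(train_s),
        "n_test": len(test_s),
        "manifest": {
            "config": cfg.to_dict(),
            "seed": cfg.training.seed,
            "cohort_hash": cohort_hash(cfg.phantom, manifest),
        },
        "train_state": {
            "epochs": mapper.train_state_.epoch,
            "stopped_early": mapper.train_state_.stopped_early,
            "best_loss": mapper.train_state_.best_loss,
        },
    }


# ----------------------------------------------------------------- suites
def table_processing_suite(base_config: dict, seeds=(0,)) -> list[AblationSpec]:
    """The image-processing ablation suite: the full pipeline plus removal of
    discretization, contrast enhancement, the median filter and the uniform
    filter, one at a time."""
    seeds = list(seeds)
    mk = lambda name, ovr: AblationSpec(name, base_config, ovr, seeds)
    return [
        mk("CTPM", []),
        mk("CTPM-disc.", [("processing.discretize", False)]),
        mk("CTPM-contr.", [("processing.contrast_enhance", False)]),
        mk("CTPM-med.", [("processing.median_filter", False)]),
        mk("CTPM-uni.", [("processing.uniform_filter", False)]),
    ]


def table_architecture_suite(base_config: dict, seeds=(0,)) -> list[AblationSpec]:
    """The 12-row architecture grid: width 3/4/5, dropout 0/0.1/0.2/0.3,
    kernel 3 vs 5, PReLU / LeakyReLU / ReLU, and removal of ROI attention,
    skip attention and the residual module."""
    seeds = list(seeds)
    base = RunConfig.from_dict(copy.deepcopy(base_config))
    k_small = 3 if base.model.kernel_size == 5 else max(3, base.model.kernel_size - 2)
    mk = lambda name, ovr: AblationSpec(name, base_config, ovr, seeds)
    w = base.model.width_multiplier
    return [
        mk(f"width {w - 1}x32", [("model.width_multiplier", w - 1)]),
        mk(f"width {w}x32 (base)", []),
        mk(f"width {w + 1}x32", [("model.width_multiplier", w + 1)]),
        mk("dropout 0", [("model.dropout_rate", 0.0)]),
        mk("dropout 0.2", [("model.dropout_rate", 0.2)]),
        mk("dropout 0.3", [("model.dropout_rate", 0.3)]),
        mk(f"kernel {k_small}", [("model.kernel_size", k_small)]),
        mk("LReLU", [("model.activation", "leaky_relu")]),
        mk("ReLU", [("model.activation", "relu")]),
        mk("no ROI attention", [("model.use_roi_attention", False)]),
        mk("no skip attention", [("model.use_skip_attention", False)]),
        mk("no residual", [("model.use_residual", False)]),
    ]


BUILTIN_SUITES = {
    "table2": table_processing_suite,
    "table3": table_architecture_suite,
}


def run_suite(
    suite: Sequence[AblationSpec],
    baseline_name: str | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run every spec x seed; aggregate per spec (mean +/- SD over seeds);
    report percent difference of mean SSIM+R against the baseline row (the
    first spec unless ``baseline_name`` is given).  Failed runs are recorded
    and the suite continues."""
    rows = []
    run_records = []
    prepared_cache: dict[str, tuple] = {}
    for spec in suite:
        try:
            cfg = spec.resolved()
            key = (
                cohort_hash(cfg.phantom, split_manifest(cfg.phantom)),
                tuple(cfg.target_shape),
                tuple(cfg.resample_spacing) if cfg.resample_spacing else None,
            )
            if key not in prepared_cache:
                prepared_cache[key] = prepare_cohort(cfg)
            results = [
                run_pipeline(cfg, seed=s, prepared=prepared_cache[key])
                for s in spec.seeds
            ]
            r = [res["summary"]["R"]["mean"] for res in results]
            s_ = [res["summary"]["SSIM"]["mean"] for res in results]
            sr = [res["summary"]["SSIM_plus_R"]["mean"] for res in results]
            rows.append({
                "name": spec.name,
                "R": float(np.mean(r)), "R_sd": float(np.std(r, ddof=1)) if len(r) > 1 else 0.0,
                "SSIM": float(np.mean(s_)),
                "SSIM_sd": float(np.std(s_, ddof=1)) if len(s_) > 1 else 0.0,
                "SSIM_plus_R": float(np.mean(sr)),
                "n_seeds": len(spec.seeds),
                "error": "",
            })
            run_records.append({"name": spec.name, "results": results})
        except Exception as exc:  # noqa: BLE001 - suite must continue
            rows.append({"name": spec.name, "R": np.nan, "R_sd": np.nan,
                         "SSIM": np.nan, "SSIM_sd": np.nan, "SSIM_plus_R": np.nan,
                         "n_seeds": len(spec.seeds), "error": f"{type(exc).__name__}: {exc}"})
            run_records.append({"name": spec.name, "error": str(exc)})
    df = pd.DataFrame(rows)
    base_idx = 0
    if baseline_name is not None:
        base_idx = int(df.index[df["name"] == baseline_name][0])
    base_score = df.loc[base_idx, "SSIM_plus_R"]
    df["percent_difference"] = [
        percent_difference(s, base_score) if np.isfinite(s) and i != base_idx
        else (0.0 if i == base_idx else np.nan)
        for i, s in enumerate(df["SSIM_plus_R"])
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "suite_results.csv", index=False)
        (out / "suite_results.md").write_text(df.to_markdown(index=False))
        (out / "runs.json").write_text(json.dumps(run_records, indent=2, default=str))
    return df


def compare_runs(run_manifests: Sequence[dict]) -> pd.DataFrame:
    """Percent-difference report: the first run is the baseline; comparison
    across different cohorts is refused."""
    if len(run_manifests) < 2:
        raise ValueError("need at least two runs to compare")
    hashes = {m["manifest"]["cohort_hash"] for m in run_manifests}
    if len(hashes) != 1:
        raise ValueError("runs were computed on different cohorts; comparison refused")
    base = run_manifests[0]["summary"]["SSIM_plus_R"]["mean"]
    rows = []
    for m in run_manifests[1:]:
        score = m["summary"]["SSIM_plus_R"]["mean"]
        rows.append({
            "seed": m["manifest"]["seed"],
            "SSIM_plus_R": score,
            "percent_difference": percent_difference(score, base),
        })
    return pd.DataFrame(rows)
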