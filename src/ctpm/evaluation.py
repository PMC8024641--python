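"""Evaluation metrics and the overall-performance protocol: masked
correlation (Spearman by default — the correlation formula applied to
average-ranked in-mask values), volumetric SSIM over a sliding uniform
window, the SSIM+R composite with percent difference against a baseline, and
low/high functional-region Dice overlap at the 0.66 threshold on the
recovered original grid."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .prep import LungSample, recover_original_grid
from .volume import ImageVolume, as_bool_mask


@dataclass
class MetricsConfig:
    correlation_mode: str = "spearman"  # spearman | pearson_raw
    ssim_window_edge: int = 7
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_L: float = 1.0  # labels live in [0, 1]
    functional_threshold: float = 0.66

    def __post_init__(self) -> None:
        if self.correlation_mode not in ("spearman", "pearson_raw"):
            raise ValueError(f"unknown correlation mode {self.correlation_mode!r}")
        if self.ssim_window_edge < 3 or self.ssim_window_edge % 2 == 0:
            raise ValueError("ssim window edge must be odd and >= 3")
        if not 0.0 < self.functional_threshold < 1.0:
            raise ValueError("functional_threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


class UndefinedCorrelation(ValueError):
    pass


def _vals(x) -> np.ndarray:
    return np.asarray(x.values if isinstance(x, ImageVolume) else x, dtype=np.float64)


# ------------------------------------------------------------ correlation
def correlation(pred, truth, mask, cfg: MetricsConfig | None = None) -> float:
    """In-mask correlation: the product-moment formula
    sum((y - ybar)(p - pbar)) / sqrt(sum((y - ybar)^2) sum((p - pbar)^2))
    applied to rank-transformed values (average ranks for ties) in spearman
    mode, or to raw values in pearson_raw mode."""
    cfg = cfg or MetricsConfig()
    m = as_bool_mask(mask)
    p, y = _vals(pred)[m], _vals(truth)[m]
    if p.size < 3:
        raise UndefinedCorrelation("need at least 3 in-mask voxels")
    if cfg.correlation_mode == "spearman":
        p, y = rankdata(p), rankdata(y)
    p = p - p.mean()
    y = y - y.mean()
    denom = np.sqrt((p * p).sum() * (y * y).sum())
    if denom == 0.0:
        raise UndefinedCorrelation("zero variance in pred or truth within the mask")
    return float((p * y).sum() / denom)


# ------------------------------------------------------------------- SSIM
def ssim(pred, truth, cfg: MetricsConfig | None = None, mask=None) -> float:
    """Volumetric SSIM: local (uniform-window) means, variances and
    cross-variance; luminance x contrast/structure terms with
    C1=(k1*L)^2, C2=(k2*L)^2; mean over in-mask window centres (all centres
    if no mask is given)."""
    cfg = cfg or MetricsConfig()
    p, y = _vals(pred), _vals(truth)
    if p.shape != y.shape:
        raise ValueError("pred / truth shape mismatch")
    w = cfg.ssim_window_edge
    if any(w > s for s in p.shape):
        raise ValueError(f"SSIM window {w} larger than volume {p.shape}")
    ssim_map = ssim_volume(p, y, cfg)
    if mask is not None:
        m = as_bool_mask(mask)
        if not m.any():
            raise ValueError("empty mask")
        return float(ssim_map[m].mean())
    return float(ssim_map.mean())


def ssim_volume(p: np.ndarray, y: np.ndarray, cfg: MetricsConfig) -> np.ndarray:
    """Per-voxel SSIM map (population window statistics, reflect boundaries)."""
    w = cfg.ssim_window_edge
    c1 = (cfg.ssim_k1 * cfg.ssim_L) ** 2
    c2 = (cfg.ssim_k2 * cfg.ssim_L) ** 2
    f = lambda v: ndimage.uniform_filter(v, size=w, mode="reflect")
    mu_p, mu_y = f(p), f(y)
    var_p = f(p * p) - mu_p**2
    var_y = f(y * y) - mu_y**2
    cov = f(p * y) - mu_p * mu_y
    lum = (2 * mu_y * mu_p + c1) / (mu_y**2 + mu_p**2 + c1)
    cs = (2 * cov + c2) / (var_y + var_p + c2)
    return lum * cs


# -------------------------------------------------------------- composite
def composite_score(r: float, ssim_value: float) -> float:
    """The SSIM+R analysis metric."""
    return float(r) + float(ssim_value)


def percent_difference(score: float, baseline: float) -> float:
    """100 * (score - baseline) / baseline; ablation below baseline is
    negative."""
    if baseline == 0:
        raise ValueError("baseline score is zero")
    return 100.0 * (score - baseline) / baseline


# -------------------------------------------------------------------- DSC
def _dsc(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0  # both regions empty on both sides
    return 2.0 * int((a & b).sum()) / (na + nb)


def functional_dsc(pred_recovered, truth_normalized, mask, cfg: MetricsConfig | None = None) -> dict:
    """Dice overlap of high (> threshold) and low (<= threshold) functional
    regions within the mask, on the recovered original grid."""
    cfg = cfg or MetricsConfig()
    m = as_bool_mask(mask)
    if not m.any():
        raise ValueError("empty mask")
    p, y = _vals(pred_recovered), _vals(truth_normalized)
    if p.shape != y.shape or p.shape != m.shape:
        raise ValueError("volumes must share the original grid")
    thr = cfg.functional_threshold
    p_high, y_high = m & (p > thr), m & (y > thr)
    p_low, y_low = m & (p <= thr), m & (y <= thr)
    return {"DSC_high": _dsc(p_high, y_high), "DSC_low": _dsc(p_low, y_low)}


# ----------------------------------------------------------------- report
@dataclass
class MetricsReport:
    per_sample: pd.DataFrame
    summary: dict = field(default_factory=dict)
    percent_difference_vs: str | None = None

    @property
    def mean_ssim_plus_r(self) -> float:
        return self.summary["SSIM_plus_R"]["mean"]

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "summary": self.summary,
            "percent_difference_vs": self.percent_difference_vs,
        }


def evaluate_sample(
    pred: ImageVolume, sample: LungSample, cfg: MetricsConfig | None = None
) -> dict:
    """All per-sample metrics: R and SSIM against the processed label on the
    network grid; DSC high/low against the normalized perfusion on the
    recovered original grid (when original-grid references are available)."""
    cfg = cfg or MetricsConfig()
    row = {"sample_id": sample.sample_id}
    row["R"] = correlation(pred, sample.perfusion, sample.roi_mask, cfg)
    row["SSIM"] = ssim(pred, sample.perfusion, cfg, mask=sample.roi_mask)
    row["SSIM_plus_R"] = composite_score(row["R"], row["SSIM"])
    if sample.perfusion_original is not None and sample.roi_mask_original is not None:
        recovered = recover_original_grid(pred, sample)
        row.update(
            functional_dsc(recovered, sample.perfusion_original, sample.roi_mask_original, cfg)
        )
    return row


def evaluate_cohort(
    predictions: Sequence[ImageVolume],
    samples: Sequence[LungSample],
    cfg: MetricsConfig | None = None,
    baseline: "MetricsReport | float | None" = None,
) -> MetricsReport:
    cfg = cfg or MetricsConfig()
    rows = [evaluate_sample(p, s, cfg) for p, s in zip(predictions, samples)]
    df = pd.DataFrame(rows)
    summary = {}
    for col in df.columns:
        if col == "sample_id":
            continue
        summary[col] = {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1))
                        if len(df) > 1 else 0.0}
    report = MetricsReport(per_sample=df, summary=summary)
    if baseline is not None:
        base = baseline.mean_ssim_plus_r if isinstance(baseline, MetricsReport) else float(baseline)
        report.summary["percent_difference"] = percent_difference(
            report.mean_ssim_plus_r, base
        )
        report.percent_difference_vs = "baseline"
    return report
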