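"""Training protocol: Kaiming-uniform initialized network, Adam, masked
binary cross-entropy on [0, 1] labels, a 500-epoch cap with the
0.2%-for-5-epochs early-stop rule, and single-seed reproducibility.

The early-stop criterion monitors the training-epoch mean loss: training
stops once the last five consecutive relative changes
``|L_e - L_{e-1}| / L_{e-1}`` are all below ``early_stop_rel_tol`` (or at
``max_epochs``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import ModelConfig, PerfusionNet, build_model
from .nn import Adam, masked_bce
from .nn.core import Tensor
from .prep import LungSample
from .volume import ImageVolume

BCE_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    max_epochs: int = 500
    early_stop_rel_tol: float = 0.002
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 < self.early_stop_rel_tol < 1.0:
            raise ValueError("early_stop_rel_tol must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainState:
    epoch: int = 0
    loss_history: list[float] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1
    best_loss: float = float("inf")
    seed: int = 0


def bce_loss(
    pred: np.ndarray | ImageVolume,
    target: np.ndarray | ImageVolume,
    mask: np.ndarray | ImageVolume | None = None,
    eps: float = BCE_EPS,
) -> float:
    """Mean in-mask binary cross-entropy, -[t log p + (1-t) log(1-p)], with
    predictions clamped to [eps, 1-eps].  Accepts soft (fractional) targets."""
    p = np.asarray(pred.values if isinstance(pred, ImageVolume) else pred, dtype=np.float64)
    t = np.asarray(target.values if isinstance(target, ImageVolume) else target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("pred / target shape mismatch")
    if mask is None:
        m = np.ones(p.shape, dtype=bool)
    else:
        mv = mask.values if isinstance(mask, ImageVolume) else mask
        m = np.asarray(mv) > 0
    if not m.any():
        raise ValueError("empty mask in BCE loss")
    pc = np.clip(p[m], eps, 1.0 - eps)
    tc = t[m]
    return float(np.mean(-(tc * np.log(pc) + (1.0 - tc) * np.log1p(-pc))))


def should_stop(loss_history: Sequence[float], cfg: TrainConfig) -> bool:
    """Early-stop decision: a pure function of the loss history."""
    if len(loss_history) == 0:
        raise ValueError("loss history is empty")
    if len(loss_history) >= cfg.max_epochs:
        return True
    n = cfg.early_stop_patience
    if len(loss_history) < n + 1:
        return False
    tail = np.asarray(loss_history[-(n + 1):], dtype=np.float64)
    prev, cur = tail[:-1], tail[1:]
    rel = np.zeros_like(cur)
    nz = prev != 0.0  # relative change from an exactly-zero loss is 0
    rel[nz] = np.abs(cur[nz] - prev[nz]) / np.abs(prev[nz])
    return bool(np.all(rel < cfg.early_stop_rel_tol))


def _stack(samples: Sequence[LungSample]):
    ct = np.stack([np.asarray(s.ct.values, dtype=np.float32) for s in samples])[:, None]
    lab = np.stack([np.asarray(s.perfusion.values, dtype=np.float32) for s in samples])[:, None]
    roi = np.stack([(np.asarray(s.roi_mask.values) > 0) for s in samples])[:, None]
    return ct, lab, roi


def train(
    net: PerfusionNet,
    samples: Sequence[LungSample],
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
) -> TrainState:
    """Train in place; returns the :class:`TrainState`.  The best-loss epoch
    weights are restored at the end.  Deterministic for a fixed seed."""
    if len(samples) == 0:
        raise ValueError("need at least one training sample")
    ct, lab, roi = _stack(samples)
    n = len(samples)
    shuffle_rng = np.random.default_rng([cfg.seed % (2**31), 201])
    net.reseed_dropout(cfg.seed)
    net.train(True)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    state = TrainState(seed=cfg.seed)
    best_state = None
    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = net(ct[idx], roi[idx])
            loss = masked_bce(pred, lab[idx], roi[idx], eps=BCE_EPS)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; try a lower learning "
                    f"rate (current {cfg.learning_rate})"
                )
            loss.backward()
            opt.step()
            batch_losses.append(lval)
        epoch_loss = float(np.mean(batch_losses))
        state.loss_history.append(epoch_loss)
        state.epoch = epoch
        if epoch_loss < state.best_loss:
            state.best_loss = epoch_loss
            state.best_epoch = epoch
            best_state = net.state_dict()
        if should_stop(state.loss_history, cfg):
            state.stopped_early = epoch < cfg.max_epochs
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "loss.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "loss"])
            for i, l in enumerate(state.loss_history, 1):
                wr.writerow([i, f"{l:.8f}"])
    return state


class PerfusionMapper:
    """fit/predict facade over the network + training protocol.

    >>> mapper = PerfusionMapper(model_cfg, train_cfg)
    >>> mapper.fit(train_samples)
    >>> vol = mapper.predict(test_sample)      # ImageVolume on network grid
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.net_: PerfusionNet | None = None
        self.train_state_: TrainState | None = None

    def fit(self, samples: Sequence[LungSample], out_dir=None) -> "PerfusionMapper":
        self.net_, _ = build_model(self.model_config, seed=self.train_config.seed)
        self.train_state_ = train(self.net_, samples, self.train_config, out_dir)
        return self

    def predict(self, sample: LungSample) -> ImageVolume:
        if self.net_ is None:
            raise RuntimeError("mapper is not fitted")
        ct = np.asarray(sample.ct.values, dtype=np.float32)[None]
        roi = (np.asarray(sample.roi_mask.values) > 0)[None]
        out = self.net_.predict(ct, roi)[0]
        return sample.ct.with_values(out.astype(np.float32))
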