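"""EFCC-Net assembly.

The classifier is a fixed pipeline over one-channel EEG epochs
(``1 x H x W``, electrodes x time):

1. point-wise (1x1) expansion of the raw epoch to ``expansion_channels``
   deep channels;
2. ``n_efcm`` shape-preserving EFCM blocks;
3. point-wise reduction to ``reduction_channels``;
4. ``1 x 2`` pooling along time (stride 2, average by default);
5. two fully connected layers (default 128 hidden units, 6 class logits).

The whole architecture, including every ablation toggle, is described by a
:class:`ModelConfig`; two configs with equal fields and seed build
bit-identical models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .efcm import BranchSpec, EFCMBlock, default_branch_specs
from .layers import BatchNorm2d, Conv2dMix, Linear, Module, set_training

__all__ = ["ModelConfig", "EFCCNet", "build_model", "count_parameters",
           "temporal_pool", "save_checkpoint", "load_checkpoint", "desk_model_config"]


@dataclass
class ModelConfig:
    """Full architectural description of an EFCC-Net instance."""

    expansion_channels: int = 40
    n_efcm: int = 2
    branch_kernels: tuple[int, ...] = (3, 5, 7)
    reduction_channels: int = 1
    pool_mode: str = "avg"
    fc1_units: int = 128
    n_classes: int = 6
    n_electrodes: int = 21
    n_times: int = 256
    branch_specs: tuple[BranchSpec, ...] | None = None
    strict_paper_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expansion_channels", "n_efcm", "reduction_channels",
                     "fc1_units", "n_electrodes", "n_times"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.pool_mode not in ("avg", "max"):
            raise ValueError(f"pool_mode must be 'avg' or 'max', got {self.pool_mode!r}")
        for k in self.branch_kernels:
            if k % 2 == 0 or k < 1:
                raise ValueError(f"branch_kernels must be odd and positive, got {k}")

    def resolved_branch_specs(self) -> list[BranchSpec]:
        if self.branch_specs is not None:
            return [dataclasses.replace(s) for s in self.branch_specs]
        return default_branch_specs(self.branch_kernels)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["branch_kernels"] = tuple(d["branch_kernels"])
        if d.get("branch_specs") is not None:
            d["branch_specs"] = tuple(BranchSpec(**s) for s in d["branch_specs"])
        return cls(**d)


def desk_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Reduced architecture for single-CPU training runs."""
    kwargs = dict(expansion_channels=16, n_efcm=1, seed=seed)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


class EFCCNet(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.expansion_channels
        use_norm = not config.strict_paper_mode
        self.expand = Conv2dMix(1, C, 1, 1, bias=True, rng=rng)
        self.expand_norm = BatchNorm2d(C) if use_norm else None
        specs = config.resolved_branch_specs()
        self.efcm_blocks = [
            EFCMBlock(C, specs, use_norm=use_norm, rng=rng) for _ in range(config.n_efcm)
        ]
        self.reduce = Conv2dMix(C, config.reduction_channels, 1, 1, bias=True, rng=rng)
        flat = config.reduction_channels * config.n_electrodes * (config.n_times // 2)
        self.fc1 = Linear(flat, config.fc1_units, rng=rng)
        self.fc2 = Linear(config.fc1_units, config.n_classes, rng=rng)

    # ------------------------------------------------------------------
    def features(self, x: Tensor) -> Tensor:
        """Pipeline up to (and including) temporal pooling; layout (C,B,H,W)."""
        h = self.expand(x)
        if self.expand_norm is not None:
            h = T.relu(self.expand_norm(h))
        for block in self.efcm_blocks:
            h = block(h)
        h = self.reduce(h)
        return T.avgpool_w2(h) if self.config.pool_mode == "avg" else T.maxpool_w2(h)

    def forward_tensor(self, batch: np.ndarray) -> Tensor:
        """Differentiable forward pass; ``batch`` is ``(B, 1, H, W)``."""
        batch = np.asarray(batch)
        if batch.ndim != 4 or batch.shape[1] != 1:
            raise ValueError(f"expected a (B, 1, H, W) batch, got {batch.shape}")
        B, _, H, W = batch.shape
        cfg = self.config
        if (H, W) != (cfg.n_electrodes, cfg.n_times):
            raise ValueError(
                f"geometry mismatch: model built for "
                f"{cfg.n_electrodes}x{cfg.n_times}, batch is {H}x{W}"
            )
        x = T.tensor(np.moveaxis(batch, 0, 1).astype(self.expand.weight.dtype))
        pooled = self.features(x)  # (r, B, H, W//2)
        flat = T.reshape(T.moveaxis(pooled, 1, 0), (B, -1))
        return self.fc2(T.relu(self.fc1(flat)))

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Inference forward pass returning ``(B, n_classes)`` logits."""
        with T.no_grad():
            return self.forward_tensor(batch).data

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(batch).argmax(axis=1)

    def train_mode(self) -> None:
        set_training(self, True)

    def eval_mode(self) -> None:
        set_training(self, False)


def build_model(config: ModelConfig) -> EFCCNet:
    """Deterministically build an EFCC-Net from its configuration."""
    return EFCCNet(config)


def count_parameters(model: EFCCNet) -> int:
    return model.n_parameters()


def temporal_pool(x: np.ndarray, mode: str = "avg") -> np.ndarray:
    """Non-overlapping ``1 x 2`` pooling along the time axis of a C x H x W map."""
    x = np.asarray(x)
    if x.shape[-1] < 2:
        raise ValueError(f"time axis must have >= 2 samples, got {x.shape[-1]}")
    if mode == "avg":
        return T.avgpool_w2(T.tensor(x)).data
    if mode == "max":
        return T.maxpool_w2(T.tensor(x)).data
    raise ValueError(f"mode must be 'avg' or 'max', got {mode!r}")


def save_checkpoint(model: EFCCNet, path) -> None:
    """Single-file checkpoint: config echo plus named weight arrays."""
    with h5py.File(path, "w") as f:
        f.create_dataset("config_json", data=model.config.to_json())
        grp = f.create_group("weights")
        for name, arr in model.named_arrays():
            if name == "config":
                continue
            grp.create_dataset(name, data=arr)


def load_checkpoint(path) -> EFCCNet:
    with h5py.File(path, "r") as f:
        raw = f["config_json"][()]
        config = ModelConfig.from_json(raw.decode() if isinstance(raw, bytes) else str(raw))
        model = build_model(config)
        arrays = {name: ds[...] for name, ds in f["weights"].items()}
    model.load_arrays(arrays)
    return model
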