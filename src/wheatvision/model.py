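"""DeepLabV3+ encoder-decoder for grain/impurity segmentation.

The encoder is a selectable backbone whose final stage uses dilated
convolution instead of stride, followed by atrous spatial pyramid pooling
(ASPP): parallel 3x3 convolutions at several dilation rates plus a 1x1
branch and a global-image-pooling branch, concatenated and projected back
by a 1x1 convolution.  The decoder bilinearly upsamples the encoder output
by 4x, concatenates it with the backbone's low-level feature map, refines
with 3x3 convolutions, and upsamples by 4x again to per-pixel class scores
(background / grain / impurity).

Training minimises unweighted per-pixel cross-entropy with Adam; the
checkpoint retained is the best-on-validation-MIOU epoch.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics as metrics_mod
from . import nn
from .backbones import BACKBONES, make_backbone
from .nn import ConvBNReLU, Module, Tensor
from .nn import autodiff as ad

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "DeepLabV3Plus",
    "build_model",
    "train",
    "predict_mask",
    "measure_speed",
    "save_checkpoint",
    "load_checkpoint",
]

N_CLASSES = 3  # background, grain, impurity


@dataclass(frozen=True)
class ModelConfig:
    """Architecture choices.

    width_multiplier scales all channel widths (1.0 = standard widths);
    output_stride is the encoder's downsampling factor (16 or 8);
    aspp_rates are the dilation rates of the parallel ASPP branches.
    """

    backbone: str = "resnet50"
    width_multiplier: float = 1.0
    output_stride: int = 16
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    n_classes: int = N_CLASSES
    input_size: tuple[int, int] = (512, 512)

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose from {sorted(BACKBONES)}"
            )
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must be in (0, 1]")
        if any(r <= 0 for r in self.aspp_rates):
            raise ValueError("aspp_rates must be positive")
        if self.n_classes != N_CLASSES:
            raise ValueError("this task has exactly 3 classes")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (the source method leaves them open)."""

    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    lr_decay_every: int = 15  # step decay: lr *= lr_decay_factor
    lr_decay_factor: float = 0.1
    weight_decay: float = 1e-4
    seed: int = 0
    init: str = "random"  # or a path to a checkpoint used as initial weights
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0; batch_size and lr positive")


class _ASPP(Module):
    def __init__(self, in_ch, out_ch, rates, rng):
        super().__init__()
        self.b1x1 = ConvBNReLU(in_ch, out_ch, 1, rng)
        self.branches = [
            ConvBNReLU(in_ch, out_ch, 3, rng, dilation=r) for r in rates
        ]
        self.pool_conv = ConvBNReLU(in_ch, out_ch, 1, rng)
        n_branches = 2 + len(rates)
        self.project = ConvBNReLU(n_branches * out_ch, out_ch, 1, rng)

    def forward(self, x):
        h, w = x.data.shape[2], x.data.shape[3]
        feats = [self.b1x1(x)] + [b(x) for b in self.branches]
        pooled = self.pool_conv(ad.global_avg_pool(x))
        feats.append(ad.broadcast_hw(pooled, h, w))
        return self.project(ad.concat(feats, axis=1))


class DeepLabV3Plus(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        wm = config.width_multiplier
        self.backbone = make_backbone(
            config.backbone, wm, config.output_stride, rng
        )
        head_ch = max(8, int(round(256 * wm)))
        low_ch = max(8, int(round(48 * wm)))
        self.aspp = _ASPP(self.backbone.out_channels, head_ch, config.aspp_rates, rng)
        self.low_project = ConvBNReLU(self.backbone.low_channels, low_ch, 1, rng)
        self.refine = nn.Sequential(
            ConvBNReLU(head_ch + low_ch, head_ch, 3, rng),
            ConvBNReLU(head_ch, head_ch, 3, rng),
        )
        self.classifier = nn.Conv2d(head_ch, config.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        low, high = self.backbone(x)
        y = self.aspp(high)
        # decoder: 4x upsample, concatenate with the low-level skip feature
        y = ad.bilinear_resize(y, low.data.shape[2], low.data.shape[3])
        y = self.refine(ad.concat([y, self.low_project(low)], axis=1))
        y = self.classifier(y)
        return ad.bilinear_resize(y, x.data.shape[2], x.data.shape[3])


def build_model(config: ModelConfig, seed: int = 0) -> DeepLabV3Plus:
    """Construct a DeepLabV3+ network; ``seed`` fixes the initial weights."""
    return DeepLabV3Plus(config, seed=seed)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 HWC images -> float32 NCHW in [-1, 1]."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    if x.ndim == 3:
        x = x[None]
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)) * 2.0 - 1.0


def _check_size(model: DeepLabV3Plus, image: np.ndarray) -> None:
    exp_h, exp_w = model.config.input_size
    if image.shape[0] != exp_h or image.shape[1] != exp_w:
        raise ValueError(
            f"image size {image.shape[1]}x{image.shape[0]} does not match the "
            f"configured input size {exp_w}x{exp_h}; resize it first"
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    model: DeepLabV3Plus,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> list[dict]:
    """Fit the network; returns the per-epoch history.

    ``train_set``/``val_set`` are lists of (RGB uint8 HWC image, label mask)
    pairs.  The model is left holding the best-on-validation weights (final
    weights when the validation set is empty).
    """
    if not train_set:
        raise ValueError("empty training set")
    if config.init != "random":
        state, _, _ = load_checkpoint(config.init, build=False)
        model.load_state_dict(state)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    images = _to_batch(np.stack([im for im, _ in train_set]))
    masks = np.stack([m for _, m in train_set]).astype(np.int64)

    history: list[dict] = []
    best_miou, best_state = -np.inf, None
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * (
            config.lr_decay_factor ** (epoch // max(1, config.lr_decay_every))
        )
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = Tensor(images[idx])
            loss = ad.softmax_cross_entropy(model(x), masks[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.item()!r} "
                    f"(lr={opt.lr}, batch={idx.tolist()})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())

        val_miou = np.nan
        if val_set:
            preds = [predict_mask(model, im) for im, _ in val_set]
            summary = metrics_mod.evaluate_set(preds, [m for _, m in val_set])
            val_miou = summary.f_miou
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_miou": val_miou}
        )
        if val_set and val_miou >= best_miou:
            best_miou = val_miou
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def predict_mask(model: DeepLabV3Plus, image: np.ndarray) -> np.ndarray:
    """Segment one RGB image into a {0,1,2} label mask (argmax over classes)."""
    _check_size(model, image)
    was_training = model.training
    model.eval()
    logits = model(Tensor(_to_batch(image)))
    if was_training:
        model.train()
    return logits.data[0].argmax(axis=0).astype(np.uint8)


def measure_speed(model: DeepLabV3Plus, images: list[np.ndarray]) -> float:
    """Mean wall-clock per-image inference time in milliseconds.

    Hardware-dependent; reported for information only.
    """
    if not images:
        raise ValueError("need at least one image")
    model.eval()
    t0 = time.perf_counter()
    for im in images:
        predict_mask(model, im)
    return (time.perf_counter() - t0) / len(images) * 1000.0


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DeepLabV3Plus, history: list[dict] | None = None):
    """Self-describing checkpoint: config + weights (+ training history)."""
    cfg = asdict(model.config)
    cfg["aspp_rates"] = list(cfg["aspp_rates"])
    cfg["input_size"] = list(cfg["input_size"])
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        __history__=np.frombuffer(
            json.dumps(history or []).encode(), dtype=np.uint8
        ),
        **model.state_dict(),
    )


def load_checkpoint(path, build: bool = True):
    """Load a checkpoint.

    With ``build=True`` returns (model, config, history); otherwise
    (state_dict, config, history).
    """
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        history = json.loads(bytes(data["__history__"]).decode())
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    cfg["aspp_rates"] = tuple(cfg["aspp_rates"])
    cfg["input_size"] = tuple(cfg["input_size"])
    config = ModelConfig(**cfg)
    if not build:
        return state, config, history
    model = build_model(config)
    model.load_state_dict(state)
    model.eval()
    return model, config, history
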