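"""Image-filtering stage: U-Net plus oracle and identity stand-ins.

The U-Net maps a motion-corrupted magnitude image to an estimate of the
motion-free image.  The ``oracle`` filter returns the paired ground-truth
reference (the ideal filter, used to test detection and reconstruction in
isolation) and ``identity`` returns its input unchanged (the null filter).

Training follows the summed-squared-error loss with Adam, per-epoch
reshuffling, halve-on-plateau learning-rate decay and early stopping; the
model state at the best validation loss is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ConfigurationError
from .nn import UNet, train
from .phantoms import ReferenceImage, as_pixels, normalize


@dataclass
class TrainingConfig:
    """Optimization schedule; defaults are the full-scale configuration."""

    max_epochs: int = 200
    steps_per_epoch: int = 650
    batch_size: int = 10
    initial_lr: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.max_epochs, self.steps_per_epoch, self.batch_size) < 1:
            raise ConfigurationError("all training counts must be positive")
        if not 0.0 < self.lr_factor < 1.0:
            raise ConfigurationError("lr_factor must be in (0, 1)")


#: Small configuration for CPU-scale experiments and the test suite.
DESK_TRAINING = TrainingConfig(max_epochs=20, steps_per_epoch=50, batch_size=4)
DESK_INPUT_SIZE = (64, 64)
DESK_BASE_FILTERS = 8


@dataclass
class FilterModel:
    """A filter of kind ``unet``, ``oracle`` or ``identity``."""

    kind: str
    net: UNet | None = None
    history: list = field(default_factory=list)

    @property
    def input_size(self):
        return None if self.net is None else self.net.input_size

    @property
    def conv_layer_count(self) -> int:
        if self.net is None:
            return 0
        return self.net.conv_layer_count


def build_unet(
    input_size: tuple[int, int] = (256, 256),
    base_filters: int = 32,
    leaky_slope: float = 0.01,
    seed: int = 0,
) -> FilterModel:
    """Construct an untrained U-Net filter (25 convolutional layers)."""
    net = UNet(input_size=input_size, base_filters=base_filters,
               leaky_slope=leaky_slope, seed=seed)
    return FilterModel(kind="unet", net=net)


def oracle_filter() -> FilterModel:
    return FilterModel(kind="oracle")


def identity_filter() -> FilterModel:
    return FilterModel(kind="identity")


def augment(image, pixel_spacing: float | None = None, seed: int = 0):
    """Random affine augmentation of a motion-free reference image.

    Draws, in order: horizontal flip (p = 0.5), translation of up to
    +-10 mm converted to pixels via ``pixel_spacing``, rotation +-5 deg,
    scaling in [0.9, 1.1] and shear in [-0.1, 0.1]; the result is
    renormalized to max 1.
    """
    pix = as_pixels(image)
    if pixel_spacing is None:
        pixel_spacing = getattr(image, "pixel_spacing", 1.0)
    if pixel_spacing <= 0:
        raise ConfigurationError("pixel_spacing must be positive")
    rng = np.random.default_rng(seed)
    flip = rng.random() < 0.5
    bound = 10.0 / pixel_spacing
    tx = rng.uniform(-bound, bound)
    ty = rng.uniform(-bound, bound)
    rot = np.deg2rad(rng.uniform(-5.0, 5.0))
    scale = 1.0 + rng.uniform(-0.1, 0.1)
    shear = rng.uniform(-0.1, 0.1)
    if flip:
        pix = pix[:, ::-1]
    h, w = pix.shape
    # forward map in (x, y) coordinates about the image center
    c, s = np.cos(rot), np.sin(rot)
    lin = scale * (np.array([[1.0, shear], [0.0, 1.0]]) @ np.array([[c, -s], [s, c]]))
    ctr = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    offset = ctr + np.array([tx, ty]) - lin @ ctr
    mat = np.eye(3)
    mat[:2, :2] = lin
    mat[:2, 2] = offset
    out = warp(pix, AffineTransform(matrix=np.linalg.inv(mat)), order=1, cval=0.0,
               preserve_range=True)
    out = normalize(out)
    if isinstance(image, ReferenceImage):
        return ReferenceImage(out, pixel_spacing=pixel_spacing)
    return out


def train_filter(pairs, cfg: TrainingConfig | None = None, val_pairs=None,
                 model: FilterModel | None = None) -> FilterModel:
    """Train a U-Net filter on (corrupted, reference) image pairs.

    ``pairs`` is a sequence of 2-D array pairs, all of one size.  If no
    ``model`` is given, a network matching the pair size is built at the
    desk-scale width.  Validation defaults to the training pairs.
    """
    if cfg is None:
        cfg = replace(DESK_TRAINING)
    pairs = [(as_pixels(a), as_pixels(b)) for a, b in pairs]
    if not pairs:
        raise ConfigurationError("training requires at least one image pair")
    shape = pairs[0][0].shape
    if any(a.shape != shape or b.shape != shape for a, b in pairs):
        raise ConfigurationError("all training images must share one size")
    if model is None:
        model = build_unet(input_size=shape, base_filters=DESK_BASE_FILTERS, seed=cfg.seed)
    if val_pairs is not None:
        val_pairs = [(as_pixels(a), as_pixels(b)) for a, b in val_pairs]
    _, history = train(model.net, pairs, cfg, val_pairs=val_pairs)
    model.history = history
    return model


def apply_filter(model: FilterModel, image, reference=None):
    """Run the filtering stage; output is clipped to >= 0 and max-normalized."""
    pix = as_pixels(image)
    if model.kind == "identity":
        out = pix.copy()
    elif model.kind == "oracle":
        if reference is None:
            raise ConfigurationError("oracle filter requires a paired reference")
        out = as_pixels(reference).copy()
    elif model.kind == "unet":
        if model.net is None:
            raise ConfigurationError("unet filter has no network attached")
        pred = model.net.forward(pix[None, None], train=False)[0, 0]
        out = normalize(pred)
    else:
        raise ConfigurationError(f"unknown filter kind: {model.kind!r}")
    if isinstance(image, ReferenceImage):
        return ReferenceImage(out, pixel_spacing=image.pixel_spacing)
    return out


def save_model(model: FilterModel, path) -> None:
    """Store a U-Net filter as .npz weights plus a JSON architecture sidecar."""
    if model.kind != "unet":
        raise ConfigurationError("only unet filters have state to save")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.net.state_dict())
    (path / "config.json").write_text(json.dumps(model.net.config()))


def load_model(path) -> FilterModel:
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    net = UNet(input_size=tuple(cfg["input_size"]), base_filters=cfg["base_filters"],
               leaky_slope=cfg["leaky_slope"], seed=cfg["seed"])
    with np.load(path / "weights.npz") as data:
        net.load_state_dict(dict(data))
    return FilterModel(kind="unet", net=net)
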