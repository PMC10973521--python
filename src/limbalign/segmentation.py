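"""Two-step encoder-decoder bone segmentation for long-leg radiographs.

Step 1 finds a region of interest (ROI) per bone on the resized whole-leg
image (311 x 932 px, intensities scaled to [0, 1]); step 2 segments each
bone inside its ROI at a per-bone working size (femoral head 470 x 470,
distal femur 740 x 540, proximal tibia 720 x 470, distal tibia 470 x 430,
talus 370 x 220).

The network is a SegNet-style symmetric encoder-decoder: the encoder of the
``full`` model is the first 13 convolutional layers of VGG16, mirrored by a
13-layer decoder that upsamples with the max-pooling indices saved by the
corresponding encoder pool, followed by a per-pixel softmax.  The ``desk``
variant keeps the same topology at 4 encoder/decoder blocks and at most 32
channels, with proportionally reduced working sizes, so that it trains in
CPU-minutes on phantom data.  Training uses SGD with momentum 0.9, learning
rate 1e-2 and mini-batches of 4, selecting the parameters with the best
validation loss.

All tensors are float32 NCHW; the implementation is pure NumPy (im2col +
GEMM convolutions with analytic backward passes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import Box

BONE_NAMES = ("femoral_head", "distal_femur", "proximal_tibia", "distal_tibia", "talus")


class SegmentationError(ValueError):
    pass


class TrainingDiverged(RuntimeError):
    def __init__(self, history):
        self.history = history
        super().__init__("training-diverged")


@dataclass(frozen=True)
class StageConfig:
    """Working sizes of the two steps, as (width, height)."""

    stage1_size: Tuple[int, int] = (311, 932)
    crop_sizes: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "femoral_head": (470, 470),
            "distal_femur": (740, 540),
            "proximal_tibia": (720, 470),
            "distal_tibia": (470, 430),
            "talus": (370, 220),
        }
    )
    roi_margin: float = 0.10  # fractional padding around each located ROI

    @classmethod
    def desk(cls) -> "StageConfig":
        """Reduced working sizes (multiples of 16 so four 2x2 pools fit)."""
        return cls(
            stage1_size=(64, 192),
            crop_sizes={
                "femoral_head": (48, 48),
                "distal_femur": (80, 64),
                "proximal_tibia": (80, 48),
                "distal_tibia": (48, 48),
                "talus": (48, 32),
            },
        )


@dataclass(frozen=True)
class TrainConfig:
    momentum: float = 0.9
    learning_rate: float = 1e-2
    max_epochs: int = 120
    mini_batch: int = 4
    seed: int = 0
    scale: str = "desk"  # "full" | "desk"

    def __post_init__(self):
        if not (0 <= self.momentum < 1):
            raise SegmentationError("momentum must be in [0, 1)")
        if self.learning_rate < 0:
            raise SegmentationError("learning rate must be >= 0")
        if self.max_epochs < 1 or self.mini_batch < 1:
            raise SegmentationError("epochs and batch size must be >= 1")


# ---------------------------------------------------------------------------
# Image resizing (bilinear for images, nearest for masks) with an explicit
# affine pixel-centre transform so predictions map back to raw coordinates.
# ---------------------------------------------------------------------------


def resize(image: np.ndarray, out_hw: Tuple[int, int], order: int = 1) -> np.ndarray:
    """Resample to (height, width) with pixel-centre alignment."""
    h, w = image.shape[:2]
    oh, ow = out_hw
    ry = (np.arange(oh) + 0.5) * (h / oh) - 0.5
    rx = (np.arange(ow) + 0.5) * (w / ow) - 0.5
    yy, xx = np.meshgrid(ry, rx, indexing="ij")
    return ndimage.map_coordinates(
        image.astype(np.float32), [yy, xx], order=order, mode="nearest"
    )


def scale_intensity(image: np.ndarray) -> Tuple[np.ndarray, List[str]]:
    """Affine map of intensities to [0, 1]; constant images map to zeros
    with a quality flag."""
    img = image.astype(np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img), ["constant-intensity"]
    return (img - lo) / (hi - lo), []


def preprocess_stage1(
    image: np.ndarray, cfg: Optional[StageConfig] = None
) -> Tuple[np.ndarray, List[str]]:
    """Whole-image preprocessing for step 1: resize + intensity scaling."""
    cfg = cfg or StageConfig()
    if image.size == 0:
        raise SegmentationError("empty image")
    w, h = cfg.stage1_size
    out = resize(image, (h, w), order=1)
    return scale_intensity(out)


@dataclass(frozen=True)
class CropTransform:
    """Affine map from crop pixel coordinates to raw-image coordinates:
    raw = origin + (crop + 0.5) * scale - 0.5 per axis."""

    ox: float
    oy: float
    sx: float
    sy: float

    def to_raw(self, x: np.ndarray, y: np.ndarray):
        return self.ox + (x + 0.5) * self.sx - 0.5, self.oy + (y + 0.5) * self.sy - 0.5

    def to_crop(self, x: np.ndarray, y: np.ndarray):
        return (x - self.ox + 0.5) / self.sx - 0.5, (y - self.oy + 0.5) / self.sy - 0.5


def crop_and_resize(
    image: np.ndarray, roi: Box, bone: str, cfg: Optional[StageConfig] = None
) -> Tuple[np.ndarray, CropTransform, List[str]]:
    """Crop a bone ROI and resize to the bone's working size.

    Returns the [0, 1]-scaled crop, the affine transform back to raw
    coordinates, and quality flags (e.g. when the ROI had to be clipped).
    """
    cfg = cfg or StageConfig()
    if bone not in cfg.crop_sizes:
        raise SegmentationError(f"unknown bone {bone!r}")
    flags: List[str] = []
    h, w = image.shape[:2]
    x0, y0 = int(np.floor(roi.xmin)), int(np.floor(roi.ymin))
    x1, y1 = int(np.ceil(roi.xmax)) + 1, int(np.ceil(roi.ymax)) + 1
    cx0, cy0, cx1, cy1 = max(x0, 0), max(y0, 0), min(x1, w), min(y1, h)
    if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1):
        flags.append("roi-clipped")
    if cx1 - cx0 < 2 or cy1 - cy0 < 2:
        raise SegmentationError("zero-area roi")
    ow, oh = cfg.crop_sizes[bone]
    patch = image[cy0:cy1, cx0:cx1]
    out = resize(patch, (oh, ow), order=1)
    scaled, f2 = scale_intensity(out)
    tf = CropTransform(
        ox=cx0, oy=cy0, sx=(cx1 - cx0) / ow, sy=(cy1 - cy0) / oh
    )
    return scaled, tf, flags + f2


def crop_mask(
    mask: np.ndarray, tf: CropTransform, out_wh: Tuple[int, int]
) -> np.ndarray:
    """Sample a raw-coordinate binary mask onto a crop grid (nearest)."""
    ow, oh = out_wh
    xs, ys = tf.to_raw(np.arange(ow), np.arange(oh))
    xi = np.clip(np.round(xs).astype(int), 0, mask.shape[1] - 1)
    yi = np.clip(np.round(ys).astype(int), 0, mask.shape[0] - 1)
    return mask[np.ix_(yi, xi)].astype(bool)


def uncrop_mask(
    mask_crop: np.ndarray, tf: CropTransform, image_shape: Tuple[int, int]
) -> np.ndarray:
    """Map a crop-frame binary mask back to raw-image coordinates."""
    h, w = image_shape
    out = np.zeros((h, w), dtype=bool)
    y0, y1 = int(tf.oy), int(tf.oy + mask_crop.shape[0] * tf.sy + 0.5)
    x0, x1 = int(tf.ox), int(tf.ox + mask_crop.shape[1] * tf.sx + 0.5)
    y1, x1 = min(y1, h), min(x1, w)
    xs, ys = tf.to_crop(np.arange(x0, x1), np.arange(y0, y1))
    xi = np.clip(np.round(xs).astype(int), 0, mask_crop.shape[1] - 1)
    yi = np.clip(np.round(ys).astype(int), 0, mask_crop.shape[0] - 1)
    out[y0:y1, x0:x1] = mask_crop[np.ix_(yi, xi)]
    return out


# ---------------------------------------------------------------------------
# NumPy layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of the zero-padded 3x3
    neighbourhoods, as a strided view copy."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, 3, 3, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return view.reshape(n, c * 9, h * w)


def _col2im(cols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    cols = cols.reshape(n, c, 3, 3, h, w)
    for i in range(3):
        for j in range(3):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, 1 : 1 + h, 1 : 1 + w]


class Conv3x3:
    """3x3 same-padding convolution with He-initialised weights."""

    def __init__(self, cin: int, cout: int, rng, relu: bool = True):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, scale, size=(cout, cin * 9)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.relu = relu
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        # one BLAS GEMM over the whole batch: (O, C9) @ (C9, N*P)
        cols = _im2col(x).transpose(1, 0, 2).reshape(c * 9, n * h * w)
        y = self.W @ cols + self.b[:, None]
        y = y.reshape(-1, n, h, w).transpose(1, 0, 2, 3)
        if self.relu:
            mask = y > 0
            y = y * mask
        else:
            mask = None
        if train:
            self._cache = (cols, x.shape, mask)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray):
        cols, xshape, mask = self._cache
        self._cache = None
        n, c, h, w = xshape
        if mask is not None:
            dy = dy * mask
        dyf = dy.transpose(1, 0, 2, 3).reshape(-1, n * h * w)
        dW = dyf @ cols.T
        db = dyf.sum(axis=1)
        dcols = (self.W.T @ dyf).reshape(c * 9, n, h * w).transpose(1, 0, 2)
        dx = _col2im(dcols, xshape)
        return dx, [dW.astype(np.float32), db.astype(np.float32)]


def _maxpool(x: np.ndarray):
    """2x2 stride-2 max pooling; returns pooled values and argmax codes."""
    n, c, h, w = x.shape
    v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _unpool(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Scatter values into a 2x-upsampled raster at the pooling indices."""
    n, c, h, w = x.shape
    flat = np.zeros((n, c, h, w, 4), dtype=x.dtype)
    np.put_along_axis(flat, idx[..., None], x[..., None], axis=-1)
    out = flat.reshape(n, c, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return out.reshape(n, c, 2 * h, 2 * w)


def _pool_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return _unpool(dy, idx)


def _unpool_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = dy.shape
    v = dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h2 // 2, w2 // 2, 4)
    return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

VGG16_BLOCKS = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]
DESK_BLOCKS = [[8], [16], [32], [32]]


class SegModel:
    """Symmetric encoder-decoder with pooling-index unpooling.

    ``blocks`` lists the encoder channel widths per block; the decoder
    mirrors them.  The final (non-ReLU) convolution maps to ``n_classes``
    and feeds a per-pixel softmax.
    """

    def __init__(
        self, scale: str = "desk", n_classes: int = 2, seed: int = 0, in_channels: int = 1
    ):
        if scale not in ("full", "desk"):
            raise SegmentationError(f"unknown scale {scale!r}")
        self.scale = scale
        self.n_classes = n_classes
        self.seed = seed
        self.in_channels = in_channels
        blocks = VGG16_BLOCKS if scale == "full" else DESK_BLOCKS
        self.blocks = blocks
        rng = np.random.default_rng(seed)
        self.enc: List[List[Conv3x3]] = []
        cin = in_channels
        for widths in blocks:
            layers = []
            for cout in widths:
                layers.append(Conv3x3(cin, cout, rng))
                cin = cout
            self.enc.append(layers)
        self.dec: List[List[Conv3x3]] = []
        for bi in range(len(blocks) - 1, -1, -1):
            widths = list(reversed(blocks[bi]))
            # The last conv of a decoder block steps down to the width of
            # the next (shallower) encoder block.
            outs = widths[1:] + [blocks[bi - 1][-1] if bi > 0 else blocks[0][0]]
            layers = []
            for cout in outs:
                layers.append(Conv3x3(cin, cout, rng))
                cin = cout
            self.dec.append(layers)
        self.classifier = Conv3x3(cin, n_classes, rng, relu=False)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self) -> List[Conv3x3]:
        out = [l for blk in self.enc for l in blk]
        out += [l for blk in self.dec for l in blk]
        out.append(self.classifier)
        return out

    def parameters(self) -> List[np.ndarray]:
        return [p for l in self._layers() for p in l.params]

    def set_parameters(self, values: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise SegmentationError("parameter count mismatch")
        for p, v in zip(params, values):
            p[...] = v

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities (N, n_classes, H, W); H, W must be divisible
        by 2**n_blocks."""
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            # (C, H, W) when C matches the input channels, else (N, H, W)
            if x.shape[0] == self.in_channels and self.in_channels > 1:
                x = x[None]
            else:
                x = x[:, None]
        x = x.astype(np.float32)
        n, _, h, w = x.shape
        div = 2 ** len(self.blocks)
        if h % div or w % div:
            raise SegmentationError(f"input size {h}x{w} not divisible by {div}")
        pool_idx = []
        for blk in self.enc:
            for layer in blk:
                x = layer.forward(x, train)
            x, idx = _maxpool(x)
            pool_idx.append(idx)
        for bi, blk in enumerate(self.dec):
            x = _unpool(x, pool_idx[len(self.dec) - 1 - bi])
            for layer in blk:
                x = layer.forward(x, train)
        logits = self.classifier.forward(x, train)
        if train:
            self._pool_idx = pool_idx
        return _softmax(logits)

    def backward(self, dlogits: np.ndarray) -> List[np.ndarray]:
        """Gradients for all parameters given d(loss)/d(logits)."""
        grads: List[np.ndarray] = []
        dy, g = self.classifier.backward(dlogits)
        grads = g
        pool_idx = self._pool_idx
        for bi in range(len(self.dec) - 1, -1, -1):
            for layer in reversed(self.dec[bi]):
                dy, g = layer.backward(dy)
                grads = g + grads
            dy = _unpool_backward(dy, pool_idx[len(self.dec) - 1 - bi])
        for bi in range(len(self.enc) - 1, -1, -1):
            dy = _pool_backward(dy, pool_idx[bi])
            for layer in reversed(self.enc[bi]):
                dy, g = layer.backward(dy)
                grads = g + grads
        return grads

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "scale": self.scale,
                "n_classes": self.n_classes,
                "seed": self.seed,
                "in_channels": self.in_channels,
            }
        )
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(
                scale=meta["scale"],
                n_classes=meta["n_classes"],
                seed=meta["seed"],
                in_channels=meta.get("in_channels", 1),
            )
            model.set_parameters(
                [data[f"p{i}"] for i in range(len(model.parameters()))]
            )
        return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(
    scale: str = "desk", n_classes: int = 2, seed: int = 0, in_channels: int = 1
) -> SegModel:
    """Construct an untrained model (deterministic given ``seed``)."""
    return SegModel(scale=scale, n_classes=n_classes, seed=seed, in_channels=in_channels)


def with_coord_channel(image: np.ndarray) -> np.ndarray:
    """Stack a normalised vertical-coordinate channel onto a 2-D image.

    On standing long-leg views each bone occupies a fixed height band, so
    an explicit y coordinate resolves the local ambiguity of shaft
    segments far from any joint."""
    h, w = image.shape
    ychan = np.repeat(np.linspace(0.0, 1.0, h, dtype=np.float32)[:, None], w, axis=1)
    return np.stack([image.astype(np.float32), ychan])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _xent_and_grad(probs: np.ndarray, labels: np.ndarray, class_weights=None):
    """Mean per-pixel cross-entropy (optionally class-weighted) and its
    gradient w.r.t. the logits."""
    n, k, h, w = probs.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    eps = 1e-9
    if class_weights is None:
        pix_w = 1.0
    else:
        cw = np.asarray(class_weights, dtype=np.float32)
        pix_w = cw[labels][:, None]  # (n, 1, h, w)
    loss = float(-(pix_w * onehot * np.log(probs + eps)).sum() / (n * h * w))
    dlogits = pix_w * (probs - onehot) / (n * h * w)
    return loss, dlogits.astype(np.float32)


def median_frequency_weights(labels, n_classes: int) -> np.ndarray:
    """Median-frequency balancing weights w_c = median(freq) / freq_c."""
    counts = np.bincount(
        np.concatenate([np.asarray(l).ravel() for l in labels]), minlength=n_classes
    ).astype(float)
    freq = counts / counts.sum()
    present = freq > 0
    med = np.median(freq[present])
    w = np.zeros(n_classes)
    w[present] = med / freq[present]
    return w


def train(
    model: SegModel,
    dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    val_dataset: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None,
    class_weights: Optional[np.ndarray] = None,
) -> Dict[str, list]:
    """SGD-with-momentum training on (image, label) pairs.

    Labels are integer class rasters (binary masks are accepted).  Records
    per-epoch training and validation loss and restores the parameters with
    the best validation loss (training loss when no validation set is
    given).  Raises ``TrainingDiverged`` when the loss turns non-finite.
    """
    if len(dataset) == 0:
        raise SegmentationError("empty dataset")
    images = np.stack([np.asarray(im, dtype=np.float32) for im, _ in dataset])
    labels = np.stack([np.asarray(lb).astype(np.int64) for _, lb in dataset])
    if val_dataset:
        vim = np.stack([np.asarray(im, dtype=np.float32) for im, _ in val_dataset])
        vlb = np.stack([np.asarray(lb).astype(np.int64) for _, lb in val_dataset])
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p) for p in params]
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, [p.copy() for p in params])

    def _eval_loss(ims, lbs) -> float:
        total, npix = 0.0, 0
        for i in range(0, len(ims), cfg.mini_batch):
            xb, yb = ims[i : i + cfg.mini_batch], lbs[i : i + cfg.mini_batch]
            probs = model.forward(xb, train=False)
            loss, _ = _xent_and_grad(probs, yb, class_weights)
            total += loss * len(xb)
            npix += len(xb)
        return total / npix

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(images))
        running = 0.0
        for i in range(0, len(order), cfg.mini_batch):
            sel = order[i : i + cfg.mini_batch]
            probs = model.forward(images[sel], train=True)
            loss, dlogits = _xent_and_grad(probs, labels[sel], class_weights)
            if not np.isfinite(loss):
                raise TrainingDiverged(history)
            running += loss * len(sel)
            grads = model.backward(dlogits)
            for p, v, g in zip(params, velocity, grads):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                p += v
        history["train_loss"].append(running / len(images))
        if val_dataset:
            vloss = _eval_loss(vim, vlb)
            history["val_loss"].append(vloss)
        else:
            vloss = history["train_loss"][-1]
        if not np.isfinite(vloss):
            raise TrainingDiverged(history)
        if vloss < best[0]:
            best = (vloss, [p.copy() for p in params])
    model.set_parameters(best[1])
    return history


# ---------------------------------------------------------------------------
# Prediction and ROI location
# ---------------------------------------------------------------------------


def predict_mask(model: SegModel, image: np.ndarray, postprocess: bool = True) -> np.ndarray:
    """Binary foreground mask: softmax argmax, then keep the largest
    connected component and fill interior holes."""
    probs = model.forward(image, train=False)[0]
    mask = probs.argmax(axis=0) > 0
    if not postprocess or not mask.any():
        return mask
    return _clean_mask(mask)


def _clean_mask(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def locate_rois(
    image: np.ndarray,
    stage1_model: SegModel,
    cfg: Optional[StageConfig] = None,
    strict: bool = True,
) -> Dict[str, Box]:
    """Per-bone ROI boxes in raw-image coordinates from the step-1 model.

    The step-1 model is multi-class (background + the five bones in the
    order of ``BONE_NAMES``).  Each bone's box bounds the largest predicted
    component, mapped back through the resize transform and padded by the
    configured margin.  Bones absent from the prediction are reported in a
    ``SegmentationError`` ("roi-not-found").
    """
    cfg = cfg or StageConfig()
    s1, _ = preprocess_stage1(image, cfg)
    if stage1_model.in_channels == 2:
        s1 = with_coord_channel(s1)
    probs = stage1_model.forward(s1, train=False)[0]
    classmap = probs.argmax(axis=0)
    h, w = image.shape[:2]
    sw, sh = cfg.stage1_size
    fx, fy = w / sw, h / sh
    rois: Dict[str, Box] = {}
    missing = []
    for ci, bone in enumerate(BONE_NAMES, start=1):
        sel = classmap == ci
        if not sel.any():
            missing.append(bone)
            continue
        sel = _clean_mask(sel)
        ys, xs = np.nonzero(sel)
        # stage-1 pixel (i, j) covers raw x in [j*fx, (j+1)*fx) etc.
        x0, x1 = xs.min() * fx, (xs.max() + 1) * fx
        y0, y1 = ys.min() * fy, (ys.max() + 1) * fy
        mx, my = cfg.roi_margin * (x1 - x0), cfg.roi_margin * (y1 - y0)
        rois[bone] = Box(
            max(x0 - mx, 0.0),
            max(y0 - my, 0.0),
            min(x1 + mx, float(w)),
            min(y1 + my, float(h)),
        )
    if missing and strict:
        raise SegmentationError("roi-not-found(" + ", ".join(missing) + ")")
    return rois
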