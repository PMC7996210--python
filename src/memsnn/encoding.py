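"""Rate-coded Poisson spike encoding and dataset I/O.

Pixel intensities are mapped to firing rates by the reciprocal rate law

    frequency(Hz) = 1 / (A - B * pixel / 255)

with ``A = 41/20`` and ``B = 2.004545`` by default, giving ~0.49 Hz for a
black pixel and ~22 Hz for a fully bright one.  Each input neuron then emits
an independent Poisson spike train over the presentation window, realised as
a Bernoulli draw per 1-ms clock bin (rate * dt <= 0.022, so the per-bin
approximation error is negligible).

The module also reads/writes IDX-format image and label files (the MNIST
container layout) and generates small labeled synthetic stroke patterns so
the whole pipeline can be exercised without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, RangeError, ShapeError

__all__ = [
    "EncoderParams",
    "ImageSample",
    "SpikeRaster",
    "pixel_to_frequency",
    "poisson_encode",
    "crop_border",
    "read_idx",
    "write_idx",
    "generate_synthetic_patterns",
]

IDX_IMAGES_MAGIC = 0x00000803  # uint8 payload, 3 dimensions
IDX_LABELS_MAGIC = 0x00000801  # uint8 payload, 1 dimension


@dataclass(frozen=True)
class EncoderParams:
    """Rate-law constants and presentation timing.

    ``A`` and ``B`` are in seconds; ``duration`` and ``dt`` in milliseconds.
    """

    A: float = 41.0 / 20.0
    B: float = 2.004545
    duration: float = 500.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.A - self.B <= 0:
            raise ValueError("rate denominator must stay positive for pixel=255")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer multiple of dt")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class ImageSample:
    """A grayscale image with an optional class label."""

    pixels: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels))
        if np.any(self.pixels < 0) or np.any(self.pixels > 255):
            raise RangeError("pixel values must lie in [0, 255]")


@dataclass(frozen=True)
class SpikeRaster:
    """Binary input-spike matrix, shape ``(n_inputs, n_bins)``."""

    spikes: np.ndarray
    dt: float

    @property
    def n_inputs(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]


def pixel_to_frequency(pixel, params: EncoderParams = EncoderParams()):
    """Firing rate in Hz for pixel value(s) in [0, 255]; increasing in pixel."""
    arr = np.asarray(pixel, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise RangeError("pixel value outside [0, 255]")
    f = 1.0 / (params.A - params.B * arr / 255.0)
    return float(f) if arr.ndim == 0 else f


def poisson_encode(image: ImageSample, params: EncoderParams, seed) -> SpikeRaster:
    """Poisson-translate an image into a binary spike raster.

    Each pixel's spike train is an independent Bernoulli process with
    per-bin probability ``rate * dt``; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    flat = image.pixels.reshape(-1)
    rates = pixel_to_frequency(flat.astype(float), params)
    p_bin = rates * params.dt / 1000.0  # dt is in ms, rates in Hz
    spikes = rng.random((flat.size, params.n_bins)) < p_bin[:, None]
    return SpikeRaster(spikes=spikes, dt=params.dt)


def crop_border(image: ImageSample) -> ImageSample:
    """Strip the 2-pixel border of a 28x28 image, leaving the central 24x24.

    The border of the handwritten-digit images is essentially always blank,
    so dropping it shrinks the input layer to 576 neurons at no cost.
    """
    if image.pixels.shape != (28, 28):
        raise ShapeError(f"expected 28x28 image, got {image.pixels.shape}")
    return ImageSample(pixels=image.pixels[2:-2, 2:-2], label=image.label)


def _read_idx_array(path, expected_magic: int, ndim: int) -> np.ndarray:
    data = Path(path).read_bytes()
    header = 4 + 4 * ndim
    if len(data) < header:
        raise FormatError(f"{path}: truncated header ({len(data)} bytes, need {header})")
    magic = int.from_bytes(data[:4], "big")
    if magic != expected_magic:
        raise FormatError(
            f"{path}: bad magic 0x{magic:08x} at offset 0 (expected 0x{expected_magic:08x})"
        )
    dims = [
        int.from_bytes(data[4 + 4 * i : 8 + 4 * i], "big") for i in range(ndim)
    ]
    n_expected = int(np.prod(dims))
    if len(data) - header != n_expected:
        raise FormatError(
            f"{path}: payload of {len(data) - header} bytes at offset {header} "
            f"does not match dimensions {dims} ({n_expected} bytes)"
        )
    return np.frombuffer(data, dtype=np.uint8, offset=header).reshape(dims)


def read_idx(images_path, labels_path) -> list[ImageSample]:
    """Read IDX image/label files (big-endian MNIST layout) into samples."""
    images = _read_idx_array(images_path, IDX_IMAGES_MAGIC, 3)
    labels = _read_idx_array(labels_path, IDX_LABELS_MAGIC, 1)
    if images.shape[0] != labels.shape[0]:
        raise FormatError(
            f"count mismatch: {images.shape[0]} images vs {labels.shape[0]} labels"
        )
    return [ImageSample(pixels=img, label=int(lab)) for img, lab in zip(images, labels)]


def write_idx(samples: Sequence[ImageSample], images_path, labels_path) -> None:
    """Write samples to IDX image/label files (inverse of :func:`read_idx`)."""
    if not samples:
        raise ValueError("cannot write an empty sample set")
    shape = samples[0].pixels.shape
    images = np.stack([np.asarray(s.pixels, dtype=np.uint8) for s in samples])
    labels = np.array([0 if s.label is None else s.label for s in samples], dtype=np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(IDX_IMAGES_MAGIC.to_bytes(4, "big"))
        for d in (len(samples), *shape):
            fh.write(int(d).to_bytes(4, "big"))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(IDX_LABELS_MAGIC.to_bytes(4, "big"))
        fh.write(len(samples).to_bytes(4, "big"))
        fh.write(labels.tobytes())


def _stroke_masks(grid_size: int) -> list[np.ndarray]:
    """Library of distinct binary stroke prototypes on a square grid.

    Horizontal and vertical bars at non-overlapping offsets are interleaved
    (so consecutive classes are near-orthogonal), followed by the two
    diagonals.
    """
    g = grid_size
    t = max(1, g // 6)  # stroke thickness
    starts = [i * 2 * t for i in range(g // (2 * t)) if i * 2 * t + t <= g]
    horizontals, verticals = [], []
    for s in starts:
        m = np.zeros((g, g), dtype=bool)
        m[s : s + t, :] = True
        horizontals.append(m)
        m = np.zeros((g, g), dtype=bool)
        m[:, s : s + t] = True
        verticals.append(m)
    masks: list[np.ndarray] = []
    for h, v in zip(horizontals, verticals):
        masks.extend([h, v])
    ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    masks.append(np.abs(ii - jj) < t)  # main diagonal
    masks.append(np.abs(ii + jj - (g - 1)) < t)  # anti-diagonal
    return masks


def generate_synthetic_patterns(
    n_classes: int,
    grid_size: int,
    n_samples: int,
    flip_noise: float,
    seed,
) -> list[ImageSample]:
    """Class-balanced noisy binary stroke patterns for desk-scale runs.

    Each class has a fixed 0/255 prototype (bars and diagonals on a
    ``grid_size x grid_size`` grid); samples are prototypes with each pixel
    flipped independently with probability ``flip_noise``.  Deterministic
    given ``seed``; sample order is a seeded shuffle so classes interleave.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    if not 0 <= flip_noise < 0.5:
        raise ValueError(f"flip_noise must lie in [0, 0.5), got {flip_noise}")
    masks = _stroke_masks(grid_size)
    if n_classes > len(masks):
        raise ValueError(
            f"only {len(masks)} distinct prototypes exist on a "
            f"{grid_size}x{grid_size} grid, requested {n_classes} classes"
        )
    protos = [np.where(masks[k], 255, 0).astype(np.uint8) for k in range(n_classes)]
    base, extra = divmod(n_samples, n_classes)
    labels = np.repeat(
        np.arange(n_classes), [base + (1 if k < extra else 0) for k in range(n_classes)]
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    samples = []
    for lab in labels:
        proto = protos[lab]
        flip = rng.random(proto.shape) < flip_noise
        pixels = np.where(flip, 255 - proto, proto).astype(np.uint8)
        samples.append(ImageSample(pixels=pixels, label=int(lab)))
    return samples


def prototype_images(n_classes: int, grid_size: int) -> list[ImageSample]:
    """The noise-free class prototypes used by the synthetic generator."""
    masks = _stroke_masks(grid_size)
    if n_classes > len(masks):
        raise ValueError(f"only {len(masks)} prototypes available")
    return [
        ImageSample(pixels=np.where(masks[k], 255, 0).astype(np.uint8), label=k)
        for k in range(n_classes)
    ]
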