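"""Signal-to-image encoding for the convolutional classifier.

Eight per-window signal sequences — the three total-acceleration axes, the
three body-acceleration axes, and the two magnitudes — are stacked as the
rows of an 8×w matrix, concatenated row-major into one length-8w sequence,
and refilled row-major into a fixed-size image (30×24 for the default
w = 90, since 8 × 90 = 720 = 30 × 24). The mapping is a fixed bijection, so
no information is lost; any consistent bijection serves a convolutional
learner equally well.

Pixel values are raw m/s² by default. Optional per-channel standardisation
(:class:`ChannelStats`, fitted on the training set) is available behind a
flag; encoder and trained model must use the same statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from actigate.preprocessing import SignalWindow, magnitude

IMAGE_HEIGHT = 30
IMAGE_WIDTH = 24

CHANNEL_ORDER = (
    "total_x",
    "total_y",
    "total_z",
    "body_x",
    "body_y",
    "body_z",
    "total_mag",
    "body_mag",
)


@dataclass
class EncodedImage:
    """A fixed-size single-channel image encoding one signal window."""

    pixels: np.ndarray
    channel_order: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be a 2-D matrix, got shape {self.pixels.shape}")


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation for optional z-scoring."""

    mean: np.ndarray  # (8,)
    sd: np.ndarray  # (8,)

    @classmethod
    def fit(cls, stacked_matrices: Sequence[np.ndarray]) -> "ChannelStats":
        data = np.concatenate([np.asarray(m) for m in stacked_matrices], axis=1)
        sd = data.std(axis=1)
        return cls(mean=data.mean(axis=1), sd=np.where(sd > 0, sd, 1.0))

    def apply(self, stacked: np.ndarray) -> np.ndarray:
        return (stacked - self.mean[:, None]) / self.sd[:, None]


def stack_channels(window: SignalWindow) -> np.ndarray:
    """The 8×w channel matrix of one window, rows in :data:`CHANNEL_ORDER`."""
    if window.total.shape != window.body.shape:
        raise ValueError("total and body series must have matching length")
    return np.vstack(
        [
            window.total.T,
            window.body.T,
            magnitude(window.total)[None, :],
            magnitude(window.body)[None, :],
        ]
    )


def to_image(
    stacked: np.ndarray, height: int = IMAGE_HEIGHT, width: int = IMAGE_WIDTH
) -> EncodedImage:
    """Reshape the 8×w channel matrix into the classifier's input image.

    Rows are concatenated top-to-bottom, then refilled row-by-row; the
    operation is bijective given the channel order and w.
    """
    stacked = np.asarray(stacked, dtype=np.float64)
    if stacked.size != height * width:
        raise ValueError(
            f"cannot reshape {stacked.shape} ({stacked.size} values) into "
            f"{height}x{width} ({height * width} values)"
        )
    return EncodedImage(pixels=stacked.reshape(height, width))


def from_image(image: EncodedImage | np.ndarray, n_channels: int = 8) -> np.ndarray:
    """Invert :func:`to_image`, recovering the channel matrix."""
    pixels = image.pixels if isinstance(image, EncodedImage) else np.asarray(image)
    if pixels.size % n_channels:
        raise ValueError(f"{pixels.size} pixels do not divide into {n_channels} channels")
    return pixels.reshape(n_channels, pixels.size // n_channels)


def encode_window(window: SignalWindow, stats: ChannelStats | None = None) -> np.ndarray:
    """Encode one window into a (height, width) image array."""
    stacked = stack_channels(window)
    if stats is not None:
        stacked = stats.apply(stacked)
    return to_image(stacked).pixels


def encode_windows(
    windows: Sequence[SignalWindow], stats: ChannelStats | None = None
) -> np.ndarray:
    """Encode windows into an (n, height, width, 1) float32 batch."""
    if not windows:
        return np.empty((0, IMAGE_HEIGHT, IMAGE_WIDTH, 1), dtype=np.float32)
    batch = np.stack([encode_window(w, stats) for w in windows])
    return batch[..., None].astype(np.float32)
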