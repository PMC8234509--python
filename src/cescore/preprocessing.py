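"""Channel preprocessing of capsule-endoscopy frames.

A raw RGB frame is converted into the three scalar channels used by every
scorer in this package:

* **gray** — Rec. 601 luminance ``0.299 R + 0.587 G + 0.114 B``, in [0, 1].
  Air bubbles are bright, debris is dark.
* **hsv_s** — HSV saturation ``(max - min) / max`` (0 where max = 0).
  Bubbles are nearly achromatic and stand out as low-saturation regions
  against the strongly coloured mucosa.
* **lab_b** — the CIELAB b* (yellow–blue opponent) channel under a D65
  white point, rescaled affinely from its representable range [-128, 127]
  to [0, 1].  Bile is strongly yellow and sits high on this channel.

The affine rescaling keeps sign information: an achromatic pixel maps to
128/255 ~ 0.502, yellow above, blue below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color

__all__ = [
    "Frame",
    "ChannelStack",
    "to_gray",
    "to_hsv_s",
    "to_lab_b",
    "stack_channels",
    "circular_mask",
]

#: Rec. 601 luma weights for R, G, B.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Normalised Lab-b value of an achromatic pixel (b* = 0).
ACHROMATIC_LAB_B = 128.0 / 255.0


@dataclass(frozen=True)
class Frame:
    """One RGB capsule frame with case/time metadata.

    ``pixels`` is an ``(H, W, 3)`` uint8 array, H = W >= 16.
    ``frame_index`` is the 0-based position in the case's time order.
    """

    pixels: np.ndarray
    case_id: str = "case"
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"frame must be an (H, W, 3) RGB array, got shape {px.shape}"
            )
        if px.shape[0] != px.shape[1] or px.shape[0] < 16:
            raise ValueError(
                f"frame must be square with side >= 16, got {px.shape[:2]}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ChannelStack:
    """The three preprocessed planes (gray, hsv_s, lab_b), each in [0, 1]."""

    gray: np.ndarray
    hsv_s: np.ndarray
    lab_b: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.gray.shape, self.hsv_s.shape, self.lab_b.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in ("gray", "hsv_s", "lab_b"):
            ch = getattr(self, name)
            if ch.min() < 0 or ch.max() > 1:
                raise ValueError(f"channel {name} has values outside [0, 1]")

    def as_array(self) -> np.ndarray:
        """Channels stacked along the last axis, order (gray, hsv_s, lab_b)."""
        return np.stack([self.gray, self.hsv_s, self.lab_b], axis=-1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.gray.shape


def _rgb_float(frame: Frame | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError(f"expected an RGB image, got shape {px.shape}")
    return px.astype(np.float64) / 255.0


def to_gray(frame: Frame | np.ndarray) -> np.ndarray:
    """Rec. 601 luminance channel, scaled to [0, 1]."""
    return _rgb_float(frame) @ GRAY_WEIGHTS


def to_hsv_s(frame: Frame | np.ndarray) -> np.ndarray:
    """HSV saturation channel, S = (max - min) / max, 0 where max = 0."""
    rgb = _rgb_float(frame)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return s


def to_lab_b(frame: Frame | np.ndarray) -> np.ndarray:
    """CIELAB b* channel (D65), rescaled from [-128, 127] to [0, 1]."""
    lab = color.rgb2lab(_rgb_float(frame))
    return np.clip((lab[..., 2] + 128.0) / 255.0, 0.0, 1.0)


def stack_channels(frame: Frame | np.ndarray) -> ChannelStack:
    """Compute all three channels for one frame, in fixed order."""
    return ChannelStack(
        gray=to_gray(frame), hsv_s=to_hsv_s(frame), lab_b=to_lab_b(frame)
    )


def circular_mask(size: int, radius_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of the inscribed circle of a ``size`` x ``size`` frame.

    Real capsule frames carry dark circular borders; synthetic frames do
    not, so this is opt-in.  ``radius_fraction`` is relative to the side.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius_fraction * size) ** 2
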