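"""Frame loading, ROI trimming, brightness-threshold denoising and ellipse augmentation.

Coordinate convention used throughout the package: images are stored row-major,
``intensities[row, col]``; rows index depth (downward), columns index lateral
position (rightward). All intervals are 0-based and half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "UltrasoundFrame",
    "RoiSpec",
    "PixelSet",
    "EllipseFilter",
    "load_frames",
    "trim",
    "denoise",
    "augment",
]

# ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class UltrasoundFrame:
    """One grayscale B-mode frame (8-bit echo intensities).

    ``offset`` records the (row, col) position of this frame's origin within
    the full acquisition frame, so coordinates of sub-images produced by
    :func:`trim` can be mapped back.
    """

    intensities: np.ndarray
    frame_index: int = 0
    time_s: float = 0.0
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("frame must be a non-empty 2-D grid")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class RoiSpec:
    """Row/column intervals (half-open) of the fascicle ("top") and
    aponeurosis ("bottom") sub-images."""

    top_rows: tuple[int, int]
    top_cols: tuple[int, int]
    bottom_rows: tuple[int, int]
    bottom_cols: tuple[int, int]

    def __post_init__(self) -> None:
        for r0, r1 in (self.top_rows, self.top_cols, self.bottom_rows, self.bottom_cols):
            if r1 <= r0 or r0 < 0:
                raise ValueError("ROI intervals must be non-empty and non-negative")
        if self.top_rows[1] > self.bottom_rows[0]:
            raise ValueError("top ROI must end at or above the bottom ROI start")

    def validate_for(self, frame: UltrasoundFrame) -> None:
        nrow, ncol = frame.shape
        if (
            self.top_rows[1] > nrow
            or self.bottom_rows[1] > nrow
            or self.top_cols[1] > ncol
            or self.bottom_cols[1] > ncol
        ):
            raise ValueError("ROI lies outside the frame")


@dataclass
class PixelSet:
    """Foreground pixels of one sub-image: parallel (col, row, intensity) arrays."""

    cols: np.ndarray
    rows: np.ndarray
    intensities: np.ndarray
    origin_roi: str = "top"

    def __post_init__(self) -> None:
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=np.int64)
        if not (len(self.cols) == len(self.rows) == len(self.intensities)):
            raise ValueError("cols, rows, intensities must have equal length")

    def __len__(self) -> int:
        return len(self.cols)

    def coords(self) -> np.ndarray:
        """(N, 2) array of (col, row) coordinates as float."""
        return np.stack([self.cols, self.rows], axis=1).astype(float)

    @staticmethod
    def empty(origin_roi: str = "top") -> "PixelSet":
        z = np.empty(0, dtype=np.int64)
        return PixelSet(z, z, z, origin_roi)


@dataclass(frozen=True)
class EllipseFilter:
    """Elliptical brightness-augmentation region.

    ``rotation_deg`` is the major-axis inclination from horizontal, positive
    when the axis rises toward the right of the screen (row decreasing).
    ``gain`` multiplies interior intensities, clipped to 255.
    """

    center: tuple[float, float]  # (col, row)
    semi_major: float
    semi_minor: float
    rotation_deg: float = 0.0
    gain: float = 1.5

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")

    def contains(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        dc = np.asarray(cols, float) - self.center[0]
        dr = np.asarray(rows, float) - self.center[1]
        # major-axis unit vector rising right: (cos, -sin) in (col, row)
        u = dc * np.cos(th) - dr * np.sin(th)
        v = dc * np.sin(th) + dr * np.cos(th)
        return (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2 <= 1.0


def _to_gray8(arr: np.ndarray) -> np.ndarray:
    """Map an arbitrary image array to 8-bit grayscale.

    Color images are collapsed by luminance; non-uint8 data is rescaled by
    max-normalization so the brightest pixel maps to 255.
    """
    a = np.asarray(arr)
    already_8bit = a.dtype == np.uint8
    if a.ndim == 3 and a.shape[-1] in (3, 4):
        a = a[..., :3].astype(float) @ _LUMA
    if already_8bit:
        if a.dtype == np.uint8:
            return a.copy()
        return np.clip(np.round(a), 0, 255).astype(np.uint8)
    a = a.astype(float)
    m = a.max()
    if m > 0:
        a = a * (255.0 / m)
    return np.clip(np.round(a), 0, 255).astype(np.uint8)


def _natural_key(p: Path) -> list:
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", p.name)]


def load_frames(path: str | Path, frame_rate: float = 20.0) -> list[UltrasoundFrame]:
    """Load an ordered frame sequence from a directory of numbered images or a
    multi-frame image file. ``time_s = frame_index / frame_rate``."""
    path = Path(path)
    arrays: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}),
            key=_natural_key,
        )
        if not files:
            raise FileNotFoundError(f"no image files found in {path}")
        for f in files:
            arrays.append(_to_gray8(iio.imread(f)))
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        raw = iio.imread(path)
        if raw.ndim == 2:
            arrays.append(_to_gray8(raw))
        elif raw.ndim == 3 and raw.shape[-1] in (3, 4):
            arrays.append(_to_gray8(raw))
        else:  # stack of frames (possibly each RGB)
            arrays.extend(_to_gray8(fr) for fr in raw)
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"frame {i} has shape {a.shape}, expected {shape}")
    return [
        UltrasoundFrame(a, frame_index=i, time_s=i / frame_rate) for i, a in enumerate(arrays)
    ]


def trim(frame: UltrasoundFrame, roi: RoiSpec) -> tuple[UltrasoundFrame, UltrasoundFrame]:
    """Crop the frame into its (top, bottom) sub-images, recording offsets."""
    roi.validate_for(frame)
    (tr0, tr1), (tc0, tc1) = roi.top_rows, roi.top_cols
    (br0, br1), (bc0, bc1) = roi.bottom_rows, roi.bottom_cols
    top = UltrasoundFrame(
        frame.intensities[tr0:tr1, tc0:tc1].copy(),
        frame.frame_index,
        frame.time_s,
        offset=(frame.offset[0] + tr0, frame.offset[1] + tc0),
    )
    bottom = UltrasoundFrame(
        frame.intensities[br0:br1, bc0:bc1].copy(),
        frame.frame_index,
        frame.time_s,
        offset=(frame.offset[0] + br0, frame.offset[1] + bc0),
    )
    return top, bottom


def denoise(sub: UltrasoundFrame, threshold: float, origin_roi: str = "top") -> PixelSet:
    """Keep exactly the pixels whose intensity is >= ``threshold``.

    Pixels strictly below the threshold are removed; equality survives.
    """
    rows, cols = np.nonzero(sub.intensities >= threshold)
    return PixelSet(cols, rows, sub.intensities[rows, cols], origin_roi)


def augment(sub: UltrasoundFrame, filt: EllipseFilter) -> UltrasoundFrame:
    """Multiply intensities inside the ellipse by the gain, clipped to 255."""
    nrow, ncol = sub.shape
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    inside = filt.contains(cols, rows)
    out = sub.intensities.astype(float)
    out[inside] = np.minimum(255.0, np.round(out[inside] * filt.gain))
    return UltrasoundFrame(out.astype(np.uint8), sub.frame_index, sub.time_s, sub.offset)
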