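"""Synthetic B-mode-like frames with known fascicle/aponeurosis geometry.

The generator emulates the structure the pipeline consumes: a bright tubular
fascicle strip (optionally split into collinear fragments) inclined 5-30° in
the top ROI, a near-horizontal bright aponeurosis band in the bottom ROI,
additive Gaussian speckle, optional high-brightness distractor blobs, an
optional shadow (attenuation) band, and a "corrupted" mode in which the
fascicle is rendered at 10% intensity while a bright decoy streak at a wrong
angle appears — the barely-visible / wrong-cluster failure cases the temporal
smoothing must absorb.

Strips are rasterized with anti-aliasing (coverage-weighted intensity) before
8-bit quantization, so sub-degree angle recovery is meaningful. Speckle is
additive Gaussian rather than physically modeled multiplicative speckle: the
pipeline only consumes thresholded brightness, so only the contrast
statistics matter. Ground truth is computed from the scene geometry alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .preprocess import RoiSpec, UltrasoundFrame

__all__ = ["SyntheticSceneSpec", "make_frame", "make_sequence", "write_frames"]


@dataclass
class SyntheticSceneSpec:
    frame_shape: tuple[int, int] = (200, 400)  # (rows, cols)
    fascicle_angle_deg: float = 10.0
    fascicle_thickness_px: float = 4.0
    fascicle_intensity: float = 200.0
    fascicle_fragments: int = 1
    fragment_gap_px: float = 8.0
    aponeurosis_angle_deg: float = -2.0
    aponeurosis_thickness_px: float = 5.0
    aponeurosis_intensity: float = 220.0
    background_mean: float = 20.0
    speckle_sigma: float = 8.0
    distractor_blobs: int = 0
    distractor_intensity: float = 240.0
    distractor_radius: float = 6.0
    shadow_band: tuple[int, int, float] | None = None  # (col0, col1, attenuation)
    corrupt: bool = False
    decoy_offset_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.fascicle_intensity, self.aponeurosis_intensity,
                  self.distractor_intensity, self.background_mean):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.fascicle_thickness_px < 1 or self.aponeurosis_thickness_px < 1:
            raise ValueError("thicknesses must be >= 1")
        if self.fascicle_fragments < 1:
            raise ValueError("fascicle_fragments must be >= 1")
        if self.shadow_band is not None and not 0 < self.shadow_band[2] <= 1:
            raise ValueError("shadow attenuation must lie in (0, 1]")

    @property
    def roi(self) -> RoiSpec:
        nrow, ncol = self.frame_shape
        split = int(round(nrow * 0.60))
        return RoiSpec(
            top_rows=(5, split - 5),
            top_cols=(0, ncol),
            bottom_rows=(split + 5, nrow - 5),
            bottom_cols=(0, ncol),
        )

    @property
    def pa_deg(self) -> float:
        return abs(self.fascicle_angle_deg - self.aponeurosis_angle_deg)


def strip_coverage(
    shape: tuple[int, int],
    center: tuple[float, float],  # (row, col)
    angle_deg: float,
    length: float,
    thickness: float,
) -> np.ndarray:
    """Anti-aliased coverage (0-1) of a rotated strip on a pixel grid."""
    nrow, ncol = shape
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), -np.sin(th)])  # (col, row): rises right for +angle
    v = np.array([np.sin(th), np.cos(th)])
    cols, rows = np.meshgrid(np.arange(ncol, dtype=float), np.arange(nrow, dtype=float))
    dc = cols - center[1]
    dr = rows - center[0]
    pu = dc * u[0] + dr * u[1]
    pv = dc * v[0] + dr * v[1]
    return np.clip(length / 2 + 0.5 - np.abs(pu), 0, 1) * np.clip(
        thickness / 2 + 0.5 - np.abs(pv), 0, 1
    )


def _disc_coverage(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    nrow, ncol = shape
    cols, rows = np.meshgrid(np.arange(ncol, dtype=float), np.arange(nrow, dtype=float))
    d = np.hypot(cols - center[1], rows - center[0])
    return np.clip(radius + 0.5 - d, 0, 1)


def _fascicle_geometry(spec: SyntheticSceneSpec) -> tuple[tuple[float, float], float]:
    """Fascicle centerline center (row, col) and total length fitting the top ROI."""
    roi = spec.roi
    height = roi.top_rows[1] - roi.top_rows[0]
    width = roi.top_cols[1] - roi.top_cols[0]
    row_c = 0.5 * (roi.top_rows[0] + roi.top_rows[1])
    col_c = 0.5 * (roi.top_cols[0] + roi.top_cols[1])
    th = abs(np.deg2rad(spec.fascicle_angle_deg))
    margin = spec.fascicle_thickness_px / 2 + 3
    half = 0.46 * width / max(np.cos(th), 1e-9)
    if np.sin(th) > 1e-9:
        half = min(half, (height / 2 - margin) / np.sin(th))
    if half < 10:
        raise ValueError("fascicle geometry does not fit inside the top ROI")
    return (row_c, col_c), 2.0 * half


def make_frame(
    spec: SyntheticSceneSpec, frame_index: int = 0, frame_rate: float = 20.0
) -> tuple[UltrasoundFrame, dict]:
    """Render one frame; returns (frame, ground-truth dict).

    Deterministic for a given spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.frame_shape
    roi = spec.roi
    structures = np.zeros(shape, dtype=float)

    # fascicle (possibly fragmented, possibly corrupted to 10% intensity)
    (row_c, col_c), total_len = _fascicle_geometry(spec)
    th = np.deg2rad(spec.fascicle_angle_deg)
    u = np.array([np.cos(th), -np.sin(th)])  # (col, row)
    n = spec.fascicle_fragments
    frag_len = (total_len - (n - 1) * spec.fragment_gap_px) / n
    if frag_len < 5:
        raise ValueError("fragments too short; reduce fragment count or gap")
    fas_intensity = spec.fascicle_intensity * (0.1 if spec.corrupt else 1.0)
    for i in range(n):
        offset = (i - (n - 1) / 2) * (frag_len + spec.fragment_gap_px)
        center = (row_c + offset * u[1], col_c + offset * u[0])
        cov = strip_coverage(shape, center, spec.fascicle_angle_deg, frag_len,
                             spec.fascicle_thickness_px)
        structures = np.maximum(structures, cov * fas_intensity)

    if spec.corrupt:
        decoy_angle = spec.fascicle_angle_deg + spec.decoy_offset_deg
        cov = strip_coverage(shape, (row_c, col_c), decoy_angle,
                             min(100.0, 0.4 * total_len), 3.0)
        structures = np.maximum(structures, cov * spec.fascicle_intensity)

    # aponeurosis spanning the bottom ROI
    b_row = 0.5 * (roi.bottom_rows[0] + roi.bottom_rows[1])
    b_col = 0.5 * (roi.bottom_cols[0] + roi.bottom_cols[1])
    b_width = roi.bottom_cols[1] - roi.bottom_cols[0]
    cov = strip_coverage(shape, (b_row, b_col), spec.aponeurosis_angle_deg,
                         0.92 * b_width, spec.aponeurosis_thickness_px)
    structures = np.maximum(structures, cov * spec.aponeurosis_intensity)

    # high-brightness distractor blobs in the top ROI, away from the fascicle
    for _ in range(spec.distractor_blobs):
        for _try in range(60):
            r = rng.uniform(roi.top_rows[0] + spec.distractor_radius + 2,
                            roi.top_rows[1] - spec.distractor_radius - 2)
            c = rng.uniform(roi.top_cols[0] + spec.distractor_radius + 2,
                            roi.top_cols[1] - spec.distractor_radius - 2)
            # distance from blob center to the fascicle centerline
            d = np.array([c - col_c, r - row_c])
            perp = abs(d[0] * u[1] - d[1] * u[0])
            if perp > spec.distractor_radius + spec.fascicle_thickness_px + 10:
                cov = _disc_coverage(shape, (r, c), spec.distractor_radius)
                structures = np.maximum(structures, cov * spec.distractor_intensity)
                break

    img = np.maximum(structures, spec.background_mean)
    if spec.shadow_band is not None:
        c0, c1, atten = spec.shadow_band
        img[:, c0:c1] *= atten
    if spec.speckle_sigma > 0:
        img = img + rng.normal(0.0, spec.speckle_sigma, size=shape)
    frame = UltrasoundFrame(
        np.clip(np.round(img), 0, 255).astype(np.uint8),
        frame_index=frame_index,
        time_s=frame_index / frame_rate,
    )
    truth = {
        "fascicle_angle_deg": spec.fascicle_angle_deg,
        "aponeurosis_angle_deg": spec.aponeurosis_angle_deg,
        "pa_deg": spec.pa_deg,
        "roi": roi,
        "corrupt": spec.corrupt,
    }
    return frame, truth


def make_sequence(
    base: SyntheticSceneSpec,
    n_frames: int,
    pa_trajectory,
    corrupt_frames=(),
    frame_rate: float = 20.0,
) -> tuple[list[UltrasoundFrame], list[dict]]:
    """Render a frame sequence realizing a pennation-angle trajectory.

    The aponeurosis is held fixed and the fascicle inclination varies so the
    per-frame PA equals the trajectory value. Frames listed in
    ``corrupt_frames`` are rendered in corrupted mode (dim fascicle plus a
    bright decoy streak). Deterministic per the base spec's seed.
    """
    pa = [float(v) for v in pa_trajectory]
    if len(pa) != n_frames:
        raise ValueError("pa_trajectory length must equal n_frames")
    corrupt = set(int(i) for i in corrupt_frames)
    frames, truths = [], []
    for t in range(n_frames):
        fas = base.aponeurosis_angle_deg + pa[t]
        spec_t = replace(
            base,
            fascicle_angle_deg=fas,
            corrupt=t in corrupt,
            seed=base.seed + 7919 * t,
        )
        frame, truth = make_frame(spec_t, frame_index=t, frame_rate=frame_rate)
        frames.append(frame)
        truths.append(truth)
    return frames, truths


def write_frames(frames: list[UltrasoundFrame], truths: list[dict], out_dir: str | Path) -> None:
    """Save frames as numbered 8-bit PNGs plus a ground-truth CSV."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fr in frames:
        iio.imwrite(out / f"frame_{fr.frame_index:04d}.png", fr.intensities)
    rows = [
        {
            "frame": fr.frame_index,
            "fascicle_angle_deg": tr["fascicle_angle_deg"],
            "aponeurosis_angle_deg": tr["aponeurosis_angle_deg"],
            "pa_deg": tr["pa_deg"],
        }
        for fr, tr in zip(frames, truths)
    ]
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
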