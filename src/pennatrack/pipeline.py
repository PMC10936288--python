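"""End-to-end stream tracking: config, per-frame detection, CSV output.

Per frame the stages run as: trim into the two ROIs; for the bottom ROI and,
per augmentation filter (the identity filter always runs first), the top ROI:
denoise -> cluster -> orient -> merge -> plausibility -> select; the
per-filter pennation angles are fused within the frame (weighted by their
viscosity against the previous final PA) and the fused value is then smoothed
across frames with the viscosity blend. Frames with no detection inherit the
previous final PA with status ``fallback``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterParams, cluster_pixels
from .preprocess import EllipseFilter, RoiSpec, UltrasoundFrame, augment, denoise, trim
from .recluster import MergeParams, cluster_angle, merge_pass, plausibility_filter
from .select import AngleEstimate, ValueWeights, compute_pa, select_target
from .temporal import (
    FusionParams,
    ViscosityParams,
    fuse_filters,
    predict_angle,
    viscosity_weight,
)

__all__ = ["PipelineConfig", "track_sequence", "write_results", "detect_roi_angle"]

logger = logging.getLogger("pennatrack")


@dataclass
class PipelineConfig:
    roi: RoiSpec
    denoise_threshold: float = 100.0
    augmentation_filters: list[EllipseFilter] = field(default_factory=list)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    merge: MergeParams = field(default_factory=MergeParams)
    value: ValueWeights | None = None  # None -> norms derived from ROI width
    viscosity: ViscosityParams = field(default_factory=ViscosityParams)
    fusion: FusionParams | None = None  # None -> fusion uses `viscosity`
    frame_rate: float = 20.0
    min_cluster_px: int = 15
    fascicle_rises_right: bool = True
    apo_max_abs_deg: float = 15.0
    smooth_target: str = "pa"  # pa | angles

    def __post_init__(self) -> None:
        if self.value is None:
            width = self.roi.top_cols[1] - self.roi.top_cols[0]
            self.value = ValueWeights(
                w=0.6, length_norm=float(width), brightness_norm=255.0 * width
            )
        if self.fusion is None:
            self.fusion = FusionParams(viscosity=self.viscosity)

    # -- flat YAML (de)serialization -------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "roi": {
                "top_rows": list(self.roi.top_rows),
                "top_cols": list(self.roi.top_cols),
                "bottom_rows": list(self.roi.bottom_rows),
                "bottom_cols": list(self.roi.bottom_cols),
            },
            "denoise_threshold": self.denoise_threshold,
            "augmentation_filters": [
                {
                    "center": list(f.center),
                    "semi_major": f.semi_major,
                    "semi_minor": f.semi_minor,
                    "rotation_deg": f.rotation_deg,
                    "gain": f.gain,
                }
                for f in self.augmentation_filters
            ],
            "clustering": asdict(self.clustering),
            "merge": asdict(self.merge),
            "value": asdict(self.value),
            "viscosity": asdict(self.viscosity),
            "fusion": {
                "epsilon": self.fusion.epsilon,
                "lambda_floor": self.fusion.lambda_floor,
            },
            "frame_rate": self.frame_rate,
            "min_cluster_px": self.min_cluster_px,
            "fascicle_rises_right": self.fascicle_rises_right,
            "apo_max_abs_deg": self.apo_max_abs_deg,
            "smooth_target": self.smooth_target,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        roi = RoiSpec(**{k: tuple(v) for k, v in doc["roi"].items()})
        filters = [
            EllipseFilter(
                center=tuple(f["center"]),
                semi_major=f["semi_major"],
                semi_minor=f["semi_minor"],
                rotation_deg=f.get("rotation_deg", 0.0),
                gain=f.get("gain", 1.5),
            )
            for f in doc.get("augmentation_filters", [])
        ]
        viscosity = ViscosityParams(**doc.get("viscosity", {}))
        fusion = FusionParams(viscosity=viscosity, **doc.get("fusion", {}))
        return cls(
            roi=roi,
            denoise_threshold=doc.get("denoise_threshold", 100.0),
            augmentation_filters=filters,
            clustering=ClusterParams(**doc.get("clustering", {})),
            merge=MergeParams(**doc.get("merge", {})),
            value=ValueWeights(**doc["value"]) if "value" in doc else None,
            viscosity=viscosity,
            fusion=fusion,
            frame_rate=doc.get("frame_rate", 20.0),
            min_cluster_px=doc.get("min_cluster_px", 15),
            fascicle_rises_right=doc.get("fascicle_rises_right", True),
            apo_max_abs_deg=doc.get("apo_max_abs_deg", 15.0),
            smooth_target=doc.get("smooth_target", "pa"),
        )


def detect_roi_angle(
    sub: UltrasoundFrame, cfg: PipelineConfig, roi_name: str
) -> float | None:
    """Run denoise -> cluster -> orient -> merge -> plausibility -> select on
    one sub-image; returns the selected cluster's angle or None."""
    px = denoise(sub, cfg.denoise_threshold, roi_name)
    if len(px) < cfg.min_cluster_px:
        return None
    clusters, _noise = cluster_pixels(px, cfg.clustering)
    clusters = [c for c in clusters if len(c) >= cfg.min_cluster_px]
    if not clusters:
        return None
    oriented = [cluster_angle(c) for c in clusters]
    n_before = len(oriented)
    merged = merge_pass(oriented, cfg.merge)
    logger.debug(
        "%s ROI: %d clusters -> %d after re-clustering", roi_name, n_before, len(merged)
    )
    if cfg.merge.plausibility:
        merged = plausibility_filter(
            merged, roi_name, cfg.fascicle_rises_right, cfg.apo_max_abs_deg
        )
    picked = select_target(merged, cfg.value)
    if picked is None:
        return None
    return picked[1]


def track_sequence(
    frames: list[UltrasoundFrame], cfg: PipelineConfig
) -> list[AngleEstimate]:
    """Track the pennation angle over an ordered frame sequence."""
    if not frames:
        raise ValueError("track_sequence needs at least one frame")
    estimates: list[AngleEstimate] = []
    prev1: float | None = None  # final PA at t-1
    prev2: float | None = None  # final PA at t-2
    for frame in frames:
        top, bottom = trim(frame, cfg.roi)
        apo = detect_roi_angle(bottom, cfg, "bottom")
        per_filter_pas: list[float] = []
        fas_angles: list[float] = []
        for filt in [None, *cfg.augmentation_filters]:
            sub = augment(top, filt) if filt is not None else top
            fas = detect_roi_angle(sub, cfg, "top")
            if fas is not None and apo is not None:
                fas_angles.append(fas)
                per_filter_pas.append(compute_pa(fas, apo))

        est = AngleEstimate(frame_index=frame.frame_index, time_s=frame.time_s)
        est.aponeurosis_angle_deg = apo if apo is not None else math.nan
        if per_filter_pas:
            est.fascicle_angle_deg = fas_angles[0]
            est.pa_raw_deg = per_filter_pas[0]
            fused, status = fuse_filters(per_filter_pas, prev1, cfg.fusion)
            if status == "fallback":
                est.pa_final_deg = float(prev1)
                est.weight_used = 0.0
                est.status = "fallback"
            elif prev1 is None:
                est.pa_final_deg = fused
                est.weight_used = 1.0
                est.status = "ok"
            else:
                predicted = predict_angle(prev1, prev2, cfg.viscosity)
                lam = viscosity_weight(fused - predicted, cfg.viscosity)
                est.pa_final_deg = lam * fused + (1.0 - lam) * predicted
                est.weight_used = lam
                est.status = "ok"
        else:
            if prev1 is not None:
                est.pa_final_deg = float(prev1)
                est.weight_used = 0.0
                est.status = "fallback"
            else:
                est.status = "no_detection"
        if not math.isnan(est.pa_final_deg):
            prev2 = prev1
            prev1 = est.pa_final_deg
        logger.info(
            "frame %d: pa_raw=%.2f pa_final=%.2f status=%s",
            frame.frame_index,
            est.pa_raw_deg,
            est.pa_final_deg,
            est.status,
        )
        estimates.append(est)
    return estimates


def write_results(estimates: list[AngleEstimate], path: str | Path) -> None:
    """Write per-frame estimates to CSV (angles rounded to 2 decimals)."""
    df = pd.DataFrame(
        [
            {
                "frame": e.frame_index,
                "time_s": e.time_s,
                "fascicle_deg": e.fascicle_angle_deg,
                "aponeurosis_deg": e.aponeurosis_angle_deg,
                "pa_raw_deg": e.pa_raw_deg,
                "pa_final_deg": e.pa_final_deg,
                "status": e.status,
            }
            for e in estimates
        ],
        columns=[
            "frame",
            "time_s",
            "fascicle_deg",
            "aponeurosis_deg",
            "pa_raw_deg",
            "pa_final_deg",
            "status",
        ],
    )
    df.to_csv(path, index=False, float_format="%.2f")
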