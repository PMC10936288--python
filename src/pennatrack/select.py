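"""Cluster value function, target selection and pennation angle.

The value of a candidate cluster is a convex combination of its normalized
endpoint length and its normalized summed echo intensity,

    V = w * L / length_norm + (1 - w) * B / brightness_norm,

with L the Euclidean distance between the cluster's left and right endpoint
pixels and B the sum of its member intensities. This mirrors how a trained
investigator favors the longest, brightest tubular streak. The exact
functional form is this package's reconstruction: it is monotone in both
ingredients (length and brightness) that the published method states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recluster import OrientedCluster

__all__ = [
    "ValueWeights",
    "AngleEstimate",
    "cluster_value",
    "select_target",
    "compute_pa",
]


@dataclass
class ValueWeights:
    w: float = 0.6
    length_norm: float = 400.0
    brightness_norm: float = 102000.0

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        if self.length_norm <= 0 or self.brightness_norm <= 0:
            raise ValueError("norms must be > 0")


@dataclass
class AngleEstimate:
    """Per-frame result of the tracking pipeline (angles in degrees)."""

    frame_index: int
    time_s: float = 0.0
    fascicle_angle_deg: float = math.nan
    aponeurosis_angle_deg: float = math.nan
    pa_raw_deg: float = math.nan
    pa_final_deg: float = math.nan
    weight_used: float = math.nan
    status: str = "ok"  # ok | fallback | no_detection


def cluster_value(c: OrientedCluster, vw: ValueWeights) -> float:
    """Value of one candidate cluster (non-negative)."""
    length = math.dist(c.p_left, c.p_right)
    brightness = float(c.cluster.members.intensities.sum())
    return vw.w * length / vw.length_norm + (1 - vw.w) * brightness / vw.brightness_norm


def select_target(
    clusters: list[OrientedCluster], vw: ValueWeights
) -> tuple[OrientedCluster, float] | None:
    """Pick the highest-value cluster and report its orientation angle.

    Ties are broken toward the larger pixel count, then the smaller cluster
    id. Returns ``None`` when there is no candidate (no-detection signal).
    """
    if not clusters:
        return None
    best = max(clusters, key=lambda oc: (cluster_value(oc, vw), len(oc), -oc.id))
    return best, best.cluster_angle_deg


def compute_pa(fascicle_angle_deg: float, aponeurosis_angle_deg: float) -> float:
    """Pennation angle from the two signed inclinations.

    With the package sign convention the fascicle and the aponeurosis incline
    to opposite sides, so the magnitude of the signed difference equals the
    sum of the two structures' inclinations away from each other — the angle
    between the fascicle and the aponeurosis. Always >= 0 and symmetric in
    its arguments.
    """
    return abs(fascicle_angle_deg - aponeurosis_angle_deg)
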