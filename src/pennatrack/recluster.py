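"""Tubular-cluster orientation and collinear merging.

Sign convention (used package-wide): an angle is positive when the structure
is shallower toward the right of the screen, i.e. its row index decreases as
the column index grows. Angles are reported in degrees within (-90, 90].

Orientation of a cluster is obtained from an intensity-weighted oriented-box
fit: the principal axis of the member pixels' second moments gives the box
direction, the extreme projections give its half-length h and half-thickness
t, and the two box diagonals make angles α₁ = θ − atan(t/h) and
α₂ = θ + atan(t/h) with the horizontal, so the cluster angle (α₁+α₂)/2
equals the axis inclination θ exactly. The four extreme member pixels in the
±45° scan directions are kept as the cluster's corner points; they anchor the
connection lines used when merging and the overlay drawings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Cluster
from .preprocess import PixelSet

__all__ = [
    "OrientedCluster",
    "MergeParams",
    "corner_points",
    "cluster_angle",
    "connection_angle",
    "merge_pass",
    "plausibility_filter",
]


@dataclass
class MergeParams:
    """Tolerances of the pairwise collinear-merge rule."""

    angle_tol_deg: float = 5.0
    connect_tol_deg: float = 5.0
    max_gap_px: float = 40.0
    plausibility: bool = True

    def __post_init__(self) -> None:
        if min(self.angle_tol_deg, self.connect_tol_deg, self.max_gap_px) < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class OrientedCluster:
    cluster: Cluster
    corners: dict[str, tuple[int, int]]  # LU, LD, RU, RD as (col, row)
    alpha1_deg: float
    alpha2_deg: float
    cluster_angle_deg: float
    p_left: tuple[int, int]
    p_right: tuple[int, int]
    axis_p_left: tuple[float, float] = (0.0, 0.0)  # fitted axis end (col, row)
    axis_p_right: tuple[float, float] = (0.0, 0.0)
    degenerate: bool = False

    @property
    def id(self) -> int:
        return self.cluster.id

    def __len__(self) -> int:
        return len(self.cluster)


def _extreme_pixel(px: PixelSet, key: np.ndarray, maximize: bool) -> tuple[int, int]:
    k = key.max() if maximize else key.min()
    idx = np.flatnonzero(key == k)
    # ties: smaller col, then smaller row
    order = np.lexsort((px.rows[idx], px.cols[idx]))
    i = idx[order[0]]
    return int(px.cols[i]), int(px.rows[i])


def corner_points(c: Cluster) -> dict[str, tuple[int, int]]:
    """Four corner member pixels of a cluster.

    LU minimizes col+row, RD maximizes col+row, RU maximizes col-row and LD
    minimizes col-row; ties are broken toward smaller col, then smaller row.
    """
    px = c.members
    if len(px) == 0:
        raise ValueError("cluster is empty")
    s = px.cols + px.rows
    d = px.cols - px.rows
    return {
        "LU": _extreme_pixel(px, s, False),
        "RD": _extreme_pixel(px, s, True),
        "RU": _extreme_pixel(px, d, True),
        "LD": _extreme_pixel(px, d, False),
    }


def _endpoints(px: PixelSet) -> tuple[tuple[int, int], tuple[int, int]]:
    left = _extreme_pixel(px, px.cols, False)
    right = _extreme_pixel(px, px.cols, True)
    return left, right


def cluster_angle(c: Cluster) -> OrientedCluster:
    """Derive a cluster's orientation from an intensity-weighted box fit."""
    px = c.members
    if len(px) == 0:
        raise ValueError("cluster is empty")
    corners = corner_points(c)
    p_left, p_right = _endpoints(px)

    xy = px.coords()
    w = px.intensities.astype(float)
    if w.sum() <= 0:
        w = np.ones(len(px))
    mean = np.average(xy, axis=0, weights=w)
    X = xy - mean
    cov = (X * w[:, None]).T @ X / w.sum()
    if len(px) == 1 or np.allclose(cov, 0):
        pt = (float(p_left[0]), float(p_left[1]))
        return OrientedCluster(
            c, corners, 0.0, 0.0, 0.0, p_left, p_right, pt, pt, degenerate=True
        )
    _, vecs = np.linalg.eigh(cov)
    u = vecs[:, -1]  # principal axis, (col, row) components
    if u[0] < 0 or (u[0] == 0 and u[1] > 0):
        u = -u
    theta = float(np.degrees(np.arctan2(-u[1], u[0])))

    proj_u = X @ u
    v = np.array([-u[1], u[0]])
    proj_v = X @ v
    h = float(np.abs(proj_u).max())
    t = float(np.abs(proj_v).max())
    if h <= 0:
        pt = (float(p_left[0]), float(p_left[1]))
        return OrientedCluster(
            c, corners, 0.0, 0.0, 0.0, p_left, p_right, pt, pt, degenerate=True
        )
    delta = float(np.degrees(np.arctan2(t, h)))
    end_a = mean - h * u  # u has non-negative col component: this is the left end
    end_b = mean + h * u
    return OrientedCluster(
        c,
        corners,
        theta - delta,
        theta + delta,
        theta,
        p_left,
        p_right,
        (float(end_a[0]), float(end_a[1])),
        (float(end_b[0]), float(end_b[1])),
    )


def _line_angle(p: tuple[float, float], q: tuple[float, float]) -> float:
    dc = q[0] - p[0]
    dr = q[1] - p[1]
    if dc < 0 or (dc == 0 and dr > 0):
        dc, dr = -dc, -dr
    return float(np.degrees(np.arctan2(-dr, dc)))


def connection_angle(left: OrientedCluster, right: OrientedCluster) -> float | None:
    """Inclination of the segment joining the left cluster's right end to the
    right cluster's left end, or ``None`` when the pair has no strict
    left/right order (not a merge candidate).

    The ends are the fitted-axis endpoints (centroid +/- half-length along the
    principal axis): for a 1-px-thin tube these are the endpoint pixels
    themselves, while for a thick tube they sit on the centerline, keeping the
    connection angle free of the half-thickness corner offset that integer
    corner pixels would introduce over short gaps."""
    if right.p_left[0] <= left.p_right[0]:
        return None
    return _line_angle(left.axis_p_right, right.axis_p_left)


def _merge_candidate(a: OrientedCluster, b: OrientedCluster, p: MergeParams) -> bool:
    if b.p_left[0] <= a.p_right[0]:
        return False
    if b.p_left[0] - a.p_right[0] > p.max_gap_px:
        return False
    if abs(a.cluster_angle_deg - b.cluster_angle_deg) > p.angle_tol_deg:
        return False
    beta = connection_angle(a, b)
    mean_angle = 0.5 * (a.cluster_angle_deg + b.cluster_angle_deg)
    return beta is not None and abs(beta - mean_angle) <= p.connect_tol_deg


def _union(a: Cluster, b: Cluster) -> Cluster:
    pa, pb = a.members, b.members
    merged = PixelSet(
        np.concatenate([pa.cols, pb.cols]),
        np.concatenate([pa.rows, pb.rows]),
        np.concatenate([pa.intensities, pb.intensities]),
        pa.origin_roi,
    )
    return Cluster(min(a.id, b.id), merged)


def merge_pass(clusters: list[OrientedCluster], p: MergeParams) -> list[OrientedCluster]:
    """Merge collinear left/right cluster pairs until no pair qualifies.

    A pair merges when one cluster lies strictly right of the other with a
    lateral gap at most ``max_gap_px``, the two cluster angles agree within
    ``angle_tol_deg``, and the connection angle agrees with their mean within
    ``connect_tol_deg``. The merged cluster is the pixel union with corners
    and angles re-derived. Idempotent at its fixpoint; conserves pixels.
    """
    out = sorted(clusters, key=lambda oc: (oc.p_left[0], oc.p_left[1], oc.id))
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(len(out)):
                if i == j:
                    continue
                if _merge_candidate(out[i], out[j], p):
                    merged = cluster_angle(_union(out[i].cluster, out[j].cluster))
                    out = [oc for k, oc in enumerate(out) if k not in (i, j)]
                    out.append(merged)
                    out.sort(key=lambda oc: (oc.p_left[0], oc.p_left[1], oc.id))
                    changed = True
                    break
            if changed:
                break
    return out


def plausibility_filter(
    clusters: list[OrientedCluster],
    roi: str,
    fascicle_rises_right: bool = True,
    apo_max_abs_deg: float = 15.0,
) -> list[OrientedCluster]:
    """Drop clusters whose slope contradicts the muscle geometry.

    In the top (fascicle) ROI the fascicle's two endpoints must slope in the
    configured direction: with ``fascicle_rises_right`` the left endpoint is
    deeper than the right one (positive angle); with the flag off, the left
    endpoint must be shallower (smaller row), which is the rule under the
    mirrored probe orientation. In the bottom ROI the aponeurosis must be
    near-horizontal: |angle| <= ``apo_max_abs_deg``.
    """
    if roi == "bottom":
        return [oc for oc in clusters if abs(oc.cluster_angle_deg) <= apo_max_abs_deg]
    if fascicle_rises_right:
        return [oc for oc in clusters if oc.p_left[1] > oc.p_right[1]]
    return [oc for oc in clusters if oc.p_left[1] < oc.p_right[1]]
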