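"""Immediate reward components for the contour-tracing agent.

Three terms are summed per step: a ternary mask-overlap improvement term,
a distance-to-boundary bonus, and a penalty for points that cluster in
place. Each term can be toggled independently so ablations are a config
switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import mask_counts

REWARD_TERMS = ("diff_iou", "edge_dist", "points_clus")


@dataclass
class RewardConfig:
    ratio: float = 0.05
    dist_threshold: float = 10.0
    std_threshold: float = 10.0
    cluster_window: int = 20
    cluster_penalty: float = 0.5
    mask_interval: int = 5
    enabled_terms: tuple[str, ...] = REWARD_TERMS
    # optional F-measure-difference term kept only for comparison tests
    use_diff_fmeasure: bool = False

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.dist_threshold <= 0 or self.std_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.cluster_window < 2:
            raise ValueError("cluster_window must be >= 2")
        if self.mask_interval < 1:
            raise ValueError("mask_interval must be >= 1")
        unknown = set(self.enabled_terms) - set(REWARD_TERMS)
        if unknown:
            raise ValueError(f"unknown reward terms: {sorted(unknown)}")
        self.enabled_terms = tuple(self.enabled_terms)

    @property
    def max_reward(self) -> float:
        hi = 0.0
        if "diff_iou" in self.enabled_terms:
            hi += 1.0
        if "edge_dist" in self.enabled_terms:
            hi += self.ratio * self.dist_threshold
        return hi

    @property
    def min_reward(self) -> float:
        lo = 0.0
        if "diff_iou" in self.enabled_terms:
            lo -= 1.0
        if "points_clus" in self.enabled_terms:
            lo -= self.cluster_penalty
        return lo


def diff_iou_reward(curr: np.ndarray, prev: np.ndarray, gt: np.ndarray) -> int:
    """Sign of IoU(curr, gt) - IoU(prev, gt), in {-1, 0, +1}.

    Compared with exact integer cross-multiplication so floating-point
    round-off can never flip a genuine tie.
    """
    ci, co, go_c = mask_counts(curr, gt)
    pi, po, go_p = mask_counts(prev, gt)
    cu = ci + co + go_c  # |curr ∪ gt|
    pu = pi + po + go_p  # |prev ∪ gt|
    # IoU := 0 for an empty union; the numerator is then 0 too, so an
    # empty union's denominator can be replaced by 1 without changing order
    lhs = ci * max(pu, 1)
    rhs = pi * max(cu, 1)
    if lhs > rhs:
        return 1
    if lhs < rhs:
        return -1
    return 0


def diff_fmeasure_reward(curr: np.ndarray, prev: np.ndarray, gt: np.ndarray) -> int:
    """Sign of Dice(curr, gt) - Dice(prev, gt); comparison alternative only."""
    ci, co, go_c = mask_counts(curr, gt)
    pi, po, go_p = mask_counts(prev, gt)
    cd = 2 * ci + co + go_c
    pd = 2 * pi + po + go_p
    lhs = 2 * ci * max(pd, 1)
    rhs = 2 * pi * max(cd, 1)
    return int(np.sign(lhs - rhs))


def edge_distance_reward(dist: float, cfg: RewardConfig) -> float:
    """ratio * (threshold - dist) when dist < threshold, else 0."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if dist < cfg.dist_threshold:
        return cfg.ratio * (cfg.dist_threshold - dist)
    return 0.0


def coordinate_dispersion(points: np.ndarray) -> float:
    """sqrt(var(rows) + var(cols)) with population variances.

    Zero iff all points coincide; the RMS distance of the points from
    their centroid.
    """
    pts = np.asarray(points, dtype=np.float64)
    return float(np.sqrt(pts[:, 0].var() + pts[:, 1].var()))


def points_clustering_reward(recent_points: list | np.ndarray, cfg: RewardConfig) -> float:
    """-penalty when the last ``cluster_window`` points are tightly bunched.

    Returns 0 while the window is not yet filled.
    """
    pts = np.atleast_2d(np.asarray(recent_points))
    if pts.size == 0:
        raise ValueError("recent_points is empty")
    if len(pts) < cfg.cluster_window:
        return 0.0
    pts = pts[-cfg.cluster_window :]
    if coordinate_dispersion(pts) < cfg.std_threshold:
        return -cfg.cluster_penalty
    return 0.0


def total_reward(
    diff_iou: float,
    edge_dist: float,
    points_clus: float,
    cfg: RewardConfig | None = None,
) -> float:
    """Sum of the enabled components; disabled terms contribute 0."""
    cfg = cfg or RewardConfig()
    r = 0.0
    if "diff_iou" in cfg.enabled_terms:
        r += diff_iou
    if "edge_dist" in cfg.enabled_terms:
        r += edge_dist
    if "points_clus" in cfg.enabled_terms:
        r += points_clus
    return r
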