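"""Deterministic contour-tracing MDP.

The agent sits on an edge point of a grayscale image and moves in one of
8 directions by a skip distance ``n``, appending each visited point to an
open contour. The observation is a small multi-layer patch centred on
the current point; the reward compares the rasterized partial contour
against the ground-truth mask and penalises stalling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import (
    Contour,
    min_edge_distance,
    normalize_symmetric,
    rasterize_contour,
    sobel_edge_map,
)
from .rewards import (
    RewardConfig,
    diff_iou_reward,
    edge_distance_reward,
    points_clustering_reward,
    total_reward,
)

# action index -> (drow, dcol) unit direction, counterclockwise from "up".
# Indices 4 (down) and 7 (up-right) are the fixed anchor assignments.
ACTION_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0),   # 0 up
    (-1, -1),  # 1 up-left
    (0, -1),   # 2 left
    (1, -1),   # 3 down-left
    (1, 0),    # 4 down
    (1, 1),    # 5 down-right
    (0, 1),    # 6 right
    (-1, 1),   # 7 up-right
)

N_ACTIONS = len(ACTION_DIRECTIONS)

# state-layer ablation presets: indices into the full 5-layer stack
# [gray, sobel, cropped prob map, past points, global prob map]
STATE_LAYER_SETS: dict[str, tuple[int, ...]] = {
    "SCGP": (0, 1, 2, 3, 4),
    "SP": (0, 1, 3),
    "SCG": (0, 1, 2, 4),
}


@dataclass
class EnvConfig:
    image_size: int = 368
    state_size: int = 51
    n_skip: int = 5
    n_skip_reduced: int = 3
    reduce_after_step: int = 100
    reduce_distance: float = 40.0
    close_distance: float = 20.0
    max_steps: int = 300
    prob_scale: int = 8
    state_layers: str = "SCGP"

    def __post_init__(self):
        if self.state_size % 2 == 0:
            raise ValueError("state_size must be odd so the point sits on a centre pixel")
        if self.state_size >= self.image_size / 2:
            raise ValueError("state_size must be well below image_size (w << W)")
        if self.n_skip_reduced > self.n_skip:
            raise ValueError("reduced skip must not exceed the initial skip")
        if self.close_distance >= self.reduce_distance:
            raise ValueError("close_distance must be below reduce_distance")
        if self.state_layers not in STATE_LAYER_SETS:
            raise ValueError(f"state_layers must be one of {sorted(STATE_LAYER_SETS)}")

    @property
    def n_state_channels(self) -> int:
        return len(STATE_LAYER_SETS[self.state_layers])


@dataclass
class EnvState:
    """The (w, h, C) observation patch plus its centre coordinate."""

    layers: np.ndarray
    center: tuple[int, int]


@dataclass
class Transition:
    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    done: bool


def apply_action(p: tuple[int, int], action: int, n: int, image_size: int) -> tuple[int, int]:
    """Move ``p`` by ``n`` pixels along the direction for ``action``, clamped."""
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"action must be in 0..{N_ACTIONS - 1}, got {action}")
    dr, dc = ACTION_DIRECTIONS[action]
    r = min(max(p[0] + dr * n, 0), image_size - 1)
    c = min(max(p[1] + dc * n, 0), image_size - 1)
    return (r, c)


def build_concatenated_image(gray: np.ndarray, prob_map: np.ndarray, scale: int = 8) -> np.ndarray:
    """Stack [gray, Sobel(gray), upsampled prob map], each mapped to [-1, 1].

    ``prob_map`` is the low-resolution edge-point score map (1/scale of
    the image) and is bilinearly upsampled to full resolution.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if prob_map.shape != (h // scale, w // scale):
        raise ValueError(
            f"prob map shape {prob_map.shape} incompatible with image {gray.shape} at scale {scale}"
        )
    from .nn.layers import BilinearResize

    up = BilinearResize(h, w).forward(np.asarray(prob_map, dtype=np.float64)[None, None])[0, 0]
    return np.stack(
        [normalize_symmetric(gray), normalize_symmetric(sobel_edge_map(gray)), normalize_symmetric(up)],
        axis=-1,
    )


def _crop_resize(img: np.ndarray, center: tuple[int, int], size: int, binary: bool) -> np.ndarray:
    """w x w window centred on ``center``; out-of-bounds windows are the
    in-bounds sub-window resized back to w x w (Fast-R-CNN-style crop)."""
    h, w = img.shape[:2]
    half = size // 2
    r0, r1 = center[0] - half, center[0] + half + 1
    c0, c1 = center[1] - half, center[1] + half + 1
    rr0, rr1 = max(r0, 0), min(r1, h)
    cc0, cc1 = max(c0, 0), min(c1, w)
    sub = img[rr0:rr1, cc0:cc1]
    if sub.shape == (size, size):
        return sub.astype(np.float64)
    if binary:
        # nearest-neighbour stretch keeps the layer strictly {0, 1}
        ri = np.clip(np.round(np.linspace(0, sub.shape[0] - 1, size)).astype(int), 0, sub.shape[0] - 1)
        ci = np.clip(np.round(np.linspace(0, sub.shape[1] - 1, size)).astype(int), 0, sub.shape[1] - 1)
        return sub[np.ix_(ri, ci)].astype(np.float64)
    from .nn.layers import BilinearResize

    return BilinearResize(size, size).forward(sub.astype(np.float64)[None, None])[0, 0]


class ContourTraceEnv:
    """Episode container; deterministic transition function.

    Ground truth is optional: without it the environment still traces
    (inference mode) but emits zero rewards.
    """

    def __init__(self, cfg: EnvConfig, reward_cfg: RewardConfig | None = None):
        self.cfg = cfg
        self.reward_cfg = reward_cfg or RewardConfig()
        self._episode_active = False

    # -- episode lifecycle -------------------------------------------------
    def reset(
        self,
        gray: np.ndarray,
        prob_map: np.ndarray,
        first_point: tuple[int, int],
        gt_mask: np.ndarray | None = None,
        gt_contour: Contour | None = None,
    ) -> EnvState:
        cfg = self.cfg
        if gray.shape != (cfg.image_size, cfg.image_size):
            raise ValueError(f"image shape {gray.shape} != ({cfg.image_size}, {cfg.image_size})")
        if not (0 <= first_point[0] < cfg.image_size and 0 <= first_point[1] < cfg.image_size):
            raise ValueError(f"first point {first_point} outside image")
        self.concat = build_concatenated_image(gray, prob_map, cfg.prob_scale)
        from .nn.layers import BilinearResize

        self.global_prob = BilinearResize(cfg.state_size, cfg.state_size).forward(
            normalize_symmetric(np.asarray(prob_map, dtype=np.float64))[None, None]
        )[0, 0]
        self.past_points = np.zeros((cfg.image_size, cfg.image_size), dtype=np.float64)
        self.past_points[first_point] = 1.0
        self.first_point = (int(first_point[0]), int(first_point[1]))
        self.trajectory: list[tuple[int, int]] = [self.first_point]
        self.gt_mask = None if gt_mask is None else np.asarray(gt_mask, dtype=bool)
        self.gt_contour = gt_contour
        self.step_count = 0
        self.n_skip = cfg.n_skip
        self.done = False
        self.done_reason: str | None = None
        self._episode_active = True
        self._first_point_mask = np.zeros((cfg.image_size, cfg.image_size), dtype=np.uint8)
        self._first_point_mask[self.first_point] = 1
        return self._observe(self.first_point)

    def _observe(self, center: tuple[int, int]) -> EnvState:
        cfg = self.cfg
        if not (0 <= center[0] < cfg.image_size and 0 <= center[1] < cfg.image_size):
            raise ValueError(f"state centre {center} outside image")
        s = cfg.state_size
        full = np.empty((s, s, 5), dtype=np.float64)
        for i in range(3):
            full[:, :, i] = _crop_resize(self.concat[:, :, i], center, s, binary=False)
        full[:, :, 3] = _crop_resize(self.past_points, center, s, binary=True)
        full[:, :, 4] = self.global_prob
        sel = STATE_LAYER_SETS[cfg.state_layers]
        return EnvState(layers=full[:, :, sel], center=(int(center[0]), int(center[1])))

    def _partial_mask(self, n_points: int) -> np.ndarray:
        """Mask of the first ``n_points`` trajectory points (>=1 -> first point only)."""
        pts = self.trajectory[: max(n_points, 1)]
        if len(pts) == 1:
            return self._first_point_mask
        return rasterize_contour(Contour(np.array(pts)), self.past_points.shape)

    def step(self, action: int) -> tuple[EnvState, float, bool, dict]:
        if not self._episode_active or self.done:
            raise RuntimeError("cannot step a finished episode; call reset first")
        cfg, rcfg = self.cfg, self.reward_cfg
        current = self.trajectory[-1]
        new_point = apply_action(current, action, self.n_skip, cfg.image_size)
        self.trajectory.append(new_point)
        self.past_points[new_point] = 1.0
        self.step_count += 1

        info: dict = {"point": new_point, "n_skip": self.n_skip}
        if self.gt_mask is not None and self.gt_contour is not None:
            m_curr = self._partial_mask(len(self.trajectory))
            m_prev = self._partial_mask(len(self.trajectory) - rcfg.mask_interval)
            r_iou = diff_iou_reward(m_curr, m_prev, self.gt_mask)
            dist = min_edge_distance(new_point, self.gt_contour)
            r_edge = edge_distance_reward(dist, rcfg)
            window = np.array(self.trajectory[-rcfg.cluster_window :])
            r_clus = points_clustering_reward(window, rcfg)
            r = total_reward(r_iou, r_edge, r_clus, rcfg)
            info.update(r_diff_iou=r_iou, r_edge_dist=r_edge, r_points_clus=r_clus)
        else:
            r = 0.0

        d_first = float(np.hypot(new_point[0] - self.first_point[0], new_point[1] - self.first_point[1]))
        if self.step_count > cfg.reduce_after_step:
            if d_first < cfg.close_distance:
                self.done = True
                self.done_reason = "closed"
            elif d_first < cfg.reduce_distance:
                self.n_skip = cfg.n_skip_reduced
        if not self.done and self.step_count >= cfg.max_steps:
            self.done = True
            self.done_reason = "max_steps"
        info["done_reason"] = self.done_reason
        return self._observe(new_point), r, self.done, info

    # -- results -----------------------------------------------------------
    def result(self) -> tuple[Contour, np.ndarray]:
        """Closed contour traced so far and its rasterized mask."""
        contour = Contour(np.array(self.trajectory), closed=self.done)
        mask = rasterize_contour(contour, self.past_points.shape)
        return contour, mask


def run_episode(
    env: ContourTraceEnv,
    policy,
    record: bool = True,
) -> tuple[Contour, np.ndarray, list[Transition]]:
    """Drive a freshly reset environment with ``policy(state) -> action``."""
    if not env._episode_active:
        raise RuntimeError("run_episode requires a reset environment")
    state = env._observe(env.trajectory[-1])
    transitions: list[Transition] = []
    done = env.done
    while not done:
        action = int(policy(state))
        next_state, r, done, _ = env.step(action)
        if record:
            transitions.append(Transition(state.layers, action, r, next_state.layers, done))
        state = next_state
    contour, mask = env.result()
    return contour, mask, transitions
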