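"""Double deep Q-network agent for next-edge-point selection.

The Q-network is a reduced 18-layer-style residual net over the multi-
layer state patch; learning uses an evaluation/target network pair, a
FIFO replay buffer sampled uniformly, an epsilon-greedy behaviour policy
and the double-Q bootstrap target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .environment import N_ACTIONS
from .metrics import average_perpendicular_distance, precision_recall_fmeasure
from .nn import (
    Adam,
    BasicBlock,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)


@dataclass
class DQNConfig:
    gamma: float = 0.9
    epsilon: float = 0.2
    replay_capacity: int = 21_000
    batch_size: int = 256
    learning_rate: float = 1e-4
    target_sync_period: int = 2_000
    stage_blocks: tuple[int, int, int, int] = (1, 1, 1, 1)
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    state_size: int = 51
    in_channels: int = 5
    n_actions: int = N_ACTIONS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.replay_capacity < self.batch_size:
            raise ValueError("replay capacity must be >= batch size")


def desk_dqn_config(**overrides) -> DQNConfig:
    """CPU-scale profile: small widths, small buffer, frequent target sync."""
    defaults = dict(
        replay_capacity=2_000,
        batch_size=16,
        learning_rate=1e-3,
        target_sync_period=200,
        stem_channels=8,
        stage_channels=(8, 8, 16, 16),
        state_size=25,
    )
    defaults.update(overrides)
    return DQNConfig(**defaults)


class QNetwork(Module):
    """Reduced residual backbone + global average pool + linear head."""

    def __init__(self, cfg: DQNConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.stem_channels
        body: list[Module] = [
            Conv2d(cfg.in_channels, c, 7, stride=2, padding=3, bias=False, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            MaxPool2d(3, 2, padding=1),
        ]
        cin = c
        for i, (cout, blocks) in enumerate(zip(cfg.stage_channels, cfg.stage_blocks)):
            stride = 1 if i == 0 else 2
            body.append(BasicBlock(cin, cout, stride=stride, rng=rng))
            for _ in range(blocks - 1):
                body.append(BasicBlock(cout, cout, stride=1, rng=rng))
            cin = cout
        body.append(GlobalAvgPool())
        self.body = Sequential(*body)
        self.fc = Linear(cin, cfg.n_actions, rng=rng)

    def forward(self, states: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, w, w) state batch -> (N, n_actions) Q-values."""
        cfg = self.cfg
        if states.ndim != 4 or states.shape[1:] != (cfg.in_channels, cfg.state_size, cfg.state_size):
            raise ValueError(
                f"expected (N, {cfg.in_channels}, {cfg.state_size}, {cfg.state_size}) states, "
                f"got {states.shape}"
            )
        return self.fc.forward(self.body.forward(states, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(self.fc.backward(dy))


def state_to_input(layers: np.ndarray) -> np.ndarray:
    """(w, h, C) observation -> (C, w, h) network input."""
    return np.ascontiguousarray(np.moveaxis(layers, -1, 0))


def select_action(q_values: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy with smallest-index tie-breaking on the greedy arm."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(len(q_values)))
    return int(np.argmax(q_values))


class ReplayBuffer:
    """Fixed-capacity FIFO ring of transitions with uniform sampling."""

    def __init__(self, capacity: int, state_shape: tuple[int, ...]):
        self.capacity = capacity
        self.states = np.zeros((capacity, *state_shape), dtype=np.float32)
        self.next_states = np.zeros((capacity, *state_shape), dtype=np.float32)
        self.actions = np.zeros(capacity, dtype=np.int64)
        self.rewards = np.zeros(capacity, dtype=np.float64)
        self.dones = np.zeros(capacity, dtype=bool)
        self.cursor = 0
        self.size = 0

    def push(self, state, action, reward, next_state, done) -> None:
        i = self.cursor
        self.states[i] = state
        self.actions[i] = action
        self.rewards[i] = reward
        self.next_states[i] = next_state
        self.dones[i] = done
        self.cursor = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform sample without replacement within the batch."""
        if self.size < batch_size:
            raise ValueError(f"buffer holds {self.size} < batch size {batch_size}")
        idx = rng.choice(self.size, size=batch_size, replace=False)
        return (
            self.states[idx].astype(np.float64),
            self.actions[idx],
            self.rewards[idx],
            self.next_states[idx].astype(np.float64),
            self.dones[idx],
        )

    @property
    def full(self) -> bool:
        return self.size == self.capacity


def compute_double_q_target(
    rewards: np.ndarray,
    dones: np.ndarray,
    next_states: np.ndarray,
    q_eval: QNetwork,
    q_targ: QNetwork,
    gamma: float,
) -> np.ndarray:
    """r + gamma * Q_targ(s', argmax_a' Q_eval(s', a')); plain r at terminals."""
    if len(rewards) == 0:
        raise ValueError("empty batch")
    targets = np.asarray(rewards, dtype=np.float64).copy()
    live = ~np.asarray(dones, dtype=bool)
    if gamma != 0.0 and live.any():
        nxt = next_states[live]
        a_star = q_eval.forward(nxt, train=False).argmax(axis=1)
        q_next = q_targ.forward(nxt, train=False)
        targets[live] += gamma * q_next[np.arange(len(a_star)), a_star]
    return targets


def td_loss_value(q_selected: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared TD error; targets are treated as constants."""
    if q_selected.shape != targets.shape:
        raise ValueError(f"size mismatch: {q_selected.shape} vs {targets.shape}")
    return float(np.mean((targets - q_selected) ** 2))


class DoubleDQN:
    """Evaluation/target network pair with Adam updates and scheduled sync."""

    def __init__(self, cfg: DQNConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.rng = rng or np.random.default_rng(cfg.seed)
        self.q_eval = QNetwork(cfg, rng=self.rng)
        self.q_targ = QNetwork(cfg, rng=np.random.default_rng(self.rng.integers(2**31)))
        self.sync_target()
        self.opt = Adam(self.q_eval.parameters(), lr=cfg.learning_rate)
        self.iteration = 0

    def sync_target(self) -> None:
        self.q_targ.load_state_dict(self.q_eval.state_dict())

    def act(self, state_layers: np.ndarray, epsilon: float | None = None) -> int:
        eps = self.cfg.epsilon if epsilon is None else epsilon
        q = self.q_eval.forward(state_to_input(state_layers)[None], train=False)[0]
        return select_action(q, eps, self.rng)

    def update(self, states, actions, rewards, next_states, dones) -> float:
        """One gradient step on the double-Q TD loss; returns the loss."""
        targets = compute_double_q_target(
            rewards, dones, next_states, self.q_eval, self.q_targ, self.cfg.gamma
        )
        q_all = self.q_eval.forward(states, train=True)
        rows = np.arange(len(actions))
        q_sel = q_all[rows, actions]
        loss = td_loss_value(q_sel, targets)
        dq = np.zeros_like(q_all)
        dq[rows, actions] = 2.0 * (q_sel - targets) / len(actions)
        self.opt.zero_grad()
        self.q_eval.backward(dq)
        self.opt.step()
        self.iteration += 1
        if self.iteration % self.cfg.target_sync_period == 0:
            self.sync_target()
        return loss


def train_agent(
    episode_factory,
    cfg: DQNConfig,
    n_updates: int,
    progress: bool = False,
    log_path: str | Path | None = None,
) -> tuple[DoubleDQN, dict[str, list]]:
    """Train the agent on episodes produced by ``episode_factory``.

    ``episode_factory(index) -> (env, first_state, gt_mask, gt_contour)``
    must return a freshly reset :class:`ContourTraceEnv`. The replay
    buffer is filled to capacity with epsilon-greedy experience before
    the first gradient step; thereafter one update is taken per
    environment step. Logs mirror the tracked training quantities:
    per-step reward components and per-episode F-measure and APD.
    """
    agent = DoubleDQN(cfg)
    shape = (cfg.in_channels, cfg.state_size, cfg.state_size)
    buffer = ReplayBuffer(cfg.replay_capacity, shape)
    logs: dict[str, list] = {
        "reward": [], "r_diff_iou": [], "r_edge_dist": [], "r_points_clus": [],
        "loss": [], "episode_f": [], "episode_apd": [],
    }

    episode_idx = 0
    env, state, gt_mask, gt_contour = episode_factory(episode_idx)
    updates = 0
    iterator = None
    if progress:
        from tqdm import tqdm

        iterator = tqdm(total=n_updates, desc="train-agent")
    log_file = open(log_path, "w") if log_path is not None else None
    if log_file:
        log_file.write("step\trow\tcol\taction\tr_diff_iou\tr_edge_dist\tr_points_clus\treward\tdone\n")
    try:
        while updates < n_updates:
            action = agent.act(state.layers)
            next_state, reward, done, info = env.step(action)
            buffer.push(
                state_to_input(state.layers), action, reward,
                state_to_input(next_state.layers), done,
            )
            logs["reward"].append(reward)
            for key in ("r_diff_iou", "r_edge_dist", "r_points_clus"):
                logs[key].append(info.get(key, 0.0))
            if log_file:
                r, c = info["point"]
                log_file.write(
                    f"{env.step_count}\t{r}\t{c}\t{action}\t{info.get('r_diff_iou', 0)}\t"
                    f"{info.get('r_edge_dist', 0.0):.4f}\t{info.get('r_points_clus', 0.0):.2f}\t"
                    f"{reward:.4f}\t{int(done)}\n"
                )
            state = next_state
            if buffer.full:
                loss = agent.update(*buffer.sample(cfg.batch_size, agent.rng))
                logs["loss"].append(loss)
                updates += 1
                if iterator is not None:
                    iterator.update(1)
            if done:
                contour, mask = env.result()
                if gt_mask is not None:
                    _, _, f = precision_recall_fmeasure(mask, gt_mask)
                    apd = average_perpendicular_distance(contour, gt_contour)
                    logs["episode_f"].append(f)
                    logs["episode_apd"].append(apd)
                episode_idx += 1
                env, state, gt_mask, gt_contour = episode_factory(episode_idx)
    finally:
        if log_file:
            log_file.close()
        if iterator is not None:
            iterator.close()
    return agent, logs


# -- checkpoints -----------------------------------------------------------

def save_agent(agent: DoubleDQN, path: str | Path) -> None:
    state = {f"eval_{k}": v for k, v in agent.q_eval.state_dict().items()}
    state.update({f"targ_{k}": v for k, v in agent.q_targ.state_dict().items()})
    state["iteration"] = np.array(agent.iteration)
    state["config_json"] = np.frombuffer(json.dumps(asdict(agent.cfg)).encode(), dtype=np.uint8)
    np.savez(Path(path), **state)


def load_agent(path: str | Path) -> DoubleDQN:
    with np.load(Path(path)) as data:
        raw = {k: data[k] for k in data.files}
    cfg_dict = json.loads(bytes(raw.pop("config_json")).decode())
    for key in ("stage_blocks", "stage_channels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = DQNConfig(**cfg_dict)
    agent = DoubleDQN(cfg)
    agent.iteration = int(raw.pop("iteration"))
    agent.q_eval.load_state_dict({k[5:]: v for k, v in raw.items() if k.startswith("eval_")})
    agent.q_targ.load_state_dict({k[5:]: v for k, v in raw.items() if k.startswith("targ_")})
    return agent
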