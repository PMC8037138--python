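"""Double-DQN machinery: targets, policy, buffer, sync, convergence."""

import numpy as np
import pytest

from edgewalk.config import desk_env_config, desk_reward_config
from edgewalk.dqn_agent import (
    DQNConfig,
    DoubleDQN,
    QNetwork,
    ReplayBuffer,
    compute_double_q_target,
    desk_dqn_config,
    load_agent,
    save_agent,
    select_action,
    state_to_input,
    td_loss_value,
    train_agent,
)
from edgewalk.environment import ContourTraceEnv
from edgewalk.first_p_net import oracle_first_point
from tests.conftest import make_phantom_set


def tiny_cfg(**overrides):
    defaults = dict(
        replay_capacity=64,
        batch_size=8,
        target_sync_period=10,
        stem_channels=4,
        stage_channels=(4, 4, 8, 8),
        state_size=25,
        seed=0,
    )
    defaults.update(overrides)
    return desk_dqn_config(**defaults)


class StubQ:
    """Fixed-output Q 'network' for hand-checkable target arithmetic."""

    def __init__(self, table):
        self.table = np.asarray(table, dtype=np.float64)

    def forward(self, states, train=False):
        idx = states[:, 0].astype(int)
        return self.table[idx]


# -- q_forward contract ----------------------------------------------------

def test_q_forward_outputs_8_actions():
    net = QNetwork(tiny_cfg())
    s = np.random.default_rng(0).normal(size=(3, 5, 25, 25))
    q = net.forward(s)
    assert q.shape == (3, 8)
    assert np.all(np.isfinite(q))


def test_q_forward_wrong_shape_raises():
    net = QNetwork(tiny_cfg())
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 5, 13, 13)))


def test_q_forward_deterministic_and_seed_sensitive():
    s = np.random.default_rng(1).normal(size=(1, 5, 25, 25))
    n1 = QNetwork(tiny_cfg(seed=1))
    n2 = QNetwork(tiny_cfg(seed=1))
    n3 = QNetwork(tiny_cfg(seed=2))
    assert np.array_equal(n1.forward(s), n2.forward(s))
    assert not np.array_equal(n1.forward(s), n3.forward(s))


# -- select_action ---------------------------------------------------------

def test_greedy_selection_deterministic():
    q = np.array([0.0, 1.0, 2.0, 9.0, 2.0, 1.0, 0.0, -1.0])
    rng = np.random.default_rng(0)
    assert all(select_action(q, 0.0, rng) == 3 for _ in range(50))


def test_uniform_when_epsilon_one():
    rng = np.random.default_rng(0)
    q = np.zeros(8)
    draws = np.array([select_action(q, 1.0, rng) for _ in range(80_000)])
    freq = np.bincount(draws, minlength=8) / len(draws)
    # binomial 99.99% CI half-width at p=1/8, n=80k is ~0.0045
    assert np.all(np.abs(freq - 0.125) < 0.005)


def test_epsilon_mixture_frequency():
    rng = np.random.default_rng(1)
    q = np.zeros(8)
    q[3] = 1.0
    draws = np.array([select_action(q, 0.2, rng) for _ in range(100_000)])
    f3 = (draws == 3).mean()
    assert abs(f3 - 0.825) < 0.01


def test_invalid_epsilon_raises():
    with pytest.raises(ValueError):
        select_action(np.zeros(8), 1.5, np.random.default_rng(0))


# -- double-Q target -------------------------------------------------------

def test_double_q_toy_differs_from_vanilla_max():
    # eval picks argmax index 1, target evaluates it as 0 -> target r + 0
    q_eval = StubQ([[1.0, 2.0]])
    q_targ = StubQ([[5.0, 0.0]])
    next_states = np.zeros((1, 1))
    t = compute_double_q_target(np.array([0.0]), np.array([False]), next_states, q_eval, q_targ, 0.9)
    assert t[0] == pytest.approx(0.0)
    vanilla = 0.0 + 0.9 * q_targ.forward(next_states)[0].max()
    assert vanilla == pytest.approx(4.5)
    assert t[0] != vanilla


def test_double_q_terminal_target_is_reward():
    q_eval = StubQ([[1.0, 2.0]])
    q_targ = StubQ([[5.0, 0.0]])
    t = compute_double_q_target(
        np.array([1.5]), np.array([True]), np.zeros((1, 1)), q_eval, q_targ, 0.9
    )
    assert t[0] == 1.5


def test_double_q_gamma_zero_collapses_to_reward():
    q_eval = StubQ([[1.0, 2.0], [3.0, 0.0]])
    q_targ = StubQ([[5.0, 0.0], [1.0, 1.0]])
    r = np.array([0.3, -0.7])
    t = compute_double_q_target(
        r, np.array([False, False]), np.array([[0.0], [1.0]]), q_eval, q_targ, 0.0
    )
    assert np.allclose(t, r)


def test_double_q_empty_batch_raises():
    with pytest.raises(ValueError):
        compute_double_q_target(np.array([]), np.array([]), np.zeros((0, 1)), None, None, 0.9)


def test_double_q_mixed_batch_hand_arithmetic():
    q_eval = StubQ([[1.0, 2.0], [0.5, 0.1]])
    q_targ = StubQ([[5.0, -1.0], [2.0, 7.0]])
    r = np.array([1.0, 2.0, 3.0])
    dones = np.array([False, False, True])
    ns = np.array([[0.0], [1.0], [0.0]])
    t = compute_double_q_target(r, dones, ns, q_eval, q_targ, 0.5)
    # s'=0: eval argmax 1 -> targ -1 => 1 + 0.5*(-1) = 0.5
    # s'=1: eval argmax 0 -> targ 2 => 2 + 0.5*2 = 3.0
    assert np.allclose(t, [0.5, 3.0, 3.0])


# -- TD loss ---------------------------------------------------------------

def test_td_loss_zero_when_equal():
    assert td_loss_value(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0


def test_td_loss_single_sample():
    assert td_loss_value(np.array([0.0]), np.array([2.0])) == 4.0


def test_td_loss_quadratic_scaling():
    q = np.array([0.0, 1.0, 2.0])
    t = np.array([1.0, 3.0, -1.0])
    assert td_loss_value(q, 2 * t - q) == pytest.approx(4 * td_loss_value(q, t))


def test_td_loss_size_mismatch_raises():
    with pytest.raises(ValueError):
        td_loss_value(np.zeros(3), np.zeros(4))


def test_td_loss_gamma_zero_terminal_batch_is_mse_to_rewards():
    q_eval = StubQ([[0.5, -0.2], [1.0, 0.3]])
    rewards = np.array([1.0, -0.5])
    dones = np.ones(2, bool)
    states = np.array([[0.0], [1.0]])
    targets = compute_double_q_target(rewards, dones, states, q_eval, q_eval, 0.0)
    q_sel = q_eval.forward(states)[np.arange(2), [0, 1]]
    assert td_loss_value(q_sel, targets) == pytest.approx(np.mean((q_sel - rewards) ** 2))


# -- replay buffer ---------------------------------------------------------

def test_buffer_fifo_overwrite():
    buf = ReplayBuffer(5, (2,))
    for i in range(6):
        buf.push(np.array([i, i]), 0, float(i), np.array([i, i]), False)
    assert buf.size == 5
    stored = sorted(buf.rewards.tolist())
    assert stored == [1.0, 2.0, 3.0, 4.0, 5.0]  # reward 0 (oldest) evicted


def test_buffer_sample_underfilled_raises():
    buf = ReplayBuffer(10, (2,))
    buf.push(np.zeros(2), 0, 0.0, np.zeros(2), False)
    with pytest.raises(ValueError):
        buf.sample(4, np.random.default_rng(0))


def test_buffer_sample_reproducible():
    buf = ReplayBuffer(10, (1,))
    for i in range(10):
        buf.push(np.array([i]), i % 8, float(i), np.array([i]), False)
    s1 = buf.sample(4, np.random.default_rng(3))
    s2 = buf.sample(4, np.random.default_rng(3))
    assert np.array_equal(s1[2], s2[2])


def test_buffer_sampling_uniform():
    buf = ReplayBuffer(10, (1,))
    for i in range(10):
        buf.push(np.array([i]), 0, float(i), np.array([i]), False)
    rng = np.random.default_rng(4)
    counts = np.zeros(10)
    for _ in range(50_000):
        (_, _, r, _, _) = buf.sample(1, rng)
        counts[int(r[0])] += 1
    freq = counts / 50_000
    assert np.all(np.abs(freq - 0.1) < 0.01)


def test_buffer_no_replacement_within_batch():
    buf = ReplayBuffer(8, (1,))
    for i in range(8):
        buf.push(np.array([i]), 0, float(i), np.array([i]), False)
    (_, _, r, _, _) = buf.sample(8, np.random.default_rng(5))
    assert len(set(r.tolist())) == 8


# -- target sync -----------------------------------------------------------

def test_sync_copies_and_decouples():
    agent = DoubleDQN(tiny_cfg())
    s = np.random.default_rng(2).normal(size=(2, 5, 25, 25))
    assert np.allclose(agent.q_eval.forward(s), agent.q_targ.forward(s))
    # one gradient step on eval must not move the target
    before = agent.q_targ.forward(s).copy()
    states = np.random.default_rng(3).normal(size=(8, 5, 25, 25))
    agent.update(states, np.zeros(8, int), np.ones(8), states, np.ones(8, bool))
    assert np.array_equal(agent.q_targ.forward(s), before)
    assert not np.allclose(agent.q_eval.forward(s), before)


def test_sync_happens_on_schedule():
    cfg = tiny_cfg(target_sync_period=3)
    agent = DoubleDQN(cfg)
    probe = np.random.default_rng(4).normal(size=(1, 5, 25, 25))
    states = np.random.default_rng(5).normal(size=(8, 5, 25, 25))
    for i in range(1, 7):
        agent.update(states, np.zeros(8, int), np.ones(8), states, np.ones(8, bool))
        eval_q = agent.q_eval.forward(probe)
        targ_q = agent.q_targ.forward(probe)
        if i % 3 == 0:
            assert np.array_equal(eval_q, targ_q)
        else:
            assert not np.array_equal(eval_q, targ_q)


# -- tabular chain MDP convergence ----------------------------------------

class ChainMDP:
    """5-state deterministic chain: right moves toward the rewarding end."""

    n_states = 5

    def reset(self):
        self.s = 0
        return self.s

    def step(self, a):
        if a == 1:
            self.s += 1
        else:
            self.s = max(self.s - 1, 0)
        if self.s == self.n_states - 1:
            return self.s, 1.0, True
        return self.s, 0.0, False


def value_iteration_q(gamma=0.9, iters=500):
    n = ChainMDP.n_states
    q = np.zeros((n, 2))
    for _ in range(iters):
        v = q.max(axis=1)
        nq = np.zeros_like(q)
        for s in range(n - 1):
            s_left = max(s - 1, 0)
            s_right = s + 1
            r_right = 1.0 if s_right == n - 1 else 0.0
            nq[s, 0] = 0.0 + gamma * v[s_left]
            nq[s, 1] = r_right + gamma * (0.0 if s_right == n - 1 else v[s_right])
        q = nq
    return q


class TabularQ:
    """Q-table exposing the same forward interface as the network."""

    def __init__(self, n_states, n_actions):
        self.table = np.zeros((n_states, n_actions))

    def forward(self, states, train=False):
        return self.table[states[:, 0].astype(int)]


def test_tabular_chain_converges_to_value_iteration():
    gamma = 0.9
    rng = np.random.default_rng(0)
    env = ChainMDP()
    q_eval = TabularQ(5, 2)
    q_targ = TabularQ(5, 2)
    buf = ReplayBuffer(500, (1,))
    s = env.reset()
    for it in range(8000):
        q = q_eval.forward(np.array([[s]]))[0]
        a = select_action(q, 0.3, rng)
        s2, r, done = env.step(a)
        buf.push(np.array([s]), a, r, np.array([s2]), done)
        s = env.reset() if done else s2
        if buf.size >= 32:
            states, actions, rewards, next_states, dones = buf.sample(32, rng)
            targets = compute_double_q_target(rewards, dones, next_states, q_eval, q_targ, gamma)
            idx = states[:, 0].astype(int)
            q_eval.table[idx, actions] += 0.1 * (targets - q_eval.table[idx, actions])
            if it % 50 == 0:
                q_targ.table = q_eval.table.copy()
    q_star = value_iteration_q(gamma)
    # terminal state 4 is never a decision state
    assert np.abs(q_eval.table[:4] - q_star[:4]).max() < 1e-2


# -- training loop on the real environment ---------------------------------

def _episode_factory(phantoms, env_cfg, rcfg, rng):
    def factory(idx):
        img, mask, con, pm = phantoms[idx % len(phantoms)]
        env = ContourTraceEnv(env_cfg, rcfg)
        state = env.reset(img, pm, oracle_first_point(con, rng), gt_mask=mask, gt_contour=con)
        return env, state, mask, con

    return factory


def test_train_agent_runs_and_learning_starts_only_when_full(phantom_set_small):
    cfg = tiny_cfg(replay_capacity=400, batch_size=8)
    factory = _episode_factory(
        phantom_set_small, desk_env_config(), desk_reward_config(), np.random.default_rng(0)
    )
    agent, logs = train_agent(factory, cfg, n_updates=5)
    # warm-up fills the buffer before the first update (which may fire on
    # the same env step that completes the fill)
    assert len(logs["reward"]) >= 400 + 5 - 1
    assert len(logs["loss"]) == 5


def test_train_agent_determinism(phantom_set_small):
    cfg = tiny_cfg(replay_capacity=120, batch_size=8, seed=9)
    losses = []
    for _ in range(2):
        factory = _episode_factory(
            phantom_set_small, desk_env_config(), desk_reward_config(), np.random.default_rng(1)
        )
        _, logs = train_agent(factory, cfg, n_updates=12)
        losses.append(tuple(logs["loss"]))
    assert losses[0] == losses[1]


def test_agent_checkpoint_round_trip(tmp_path, phantom_set_small):
    cfg = tiny_cfg(replay_capacity=80, batch_size=8)
    factory = _episode_factory(
        phantom_set_small, desk_env_config(), desk_reward_config(), np.random.default_rng(2)
    )
    agent, _ = train_agent(factory, cfg, n_updates=3)
    path = tmp_path / "agent.npz"
    save_agent(agent, path)
    loaded = load_agent(path)
    s = np.random.default_rng(6).normal(size=(2, 5, 25, 25))
    assert np.array_equal(agent.q_eval.forward(s), loaded.q_eval.forward(s))
    assert np.array_equal(agent.q_targ.forward(s), loaded.q_targ.forward(s))
    assert loaded.iteration == agent.iteration


def test_config_validation():
    with pytest.raises(ValueError):
        DQNConfig(gamma=1.5)
    with pytest.raises(ValueError):
        DQNConfig(replay_capacity=10, batch_size=32)
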