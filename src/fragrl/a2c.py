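"""Advantage actor-critic loop over fragment-replacement episodes.

Each episode starts from a seed molecule's decomposition and applies ``Time``
single-fragment replacements.  A replacement that breaks chemistry earns zero
reward and the state reverts to the previous valid one.  Updates use one-step
TD advantages (synchronous, single worker).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly import (
    AssemblyError,
    IncompatibleFragmentError,
    MoleculeState,
    assemble_raw,
    decompose,
    replace_fragment,
    rewire_fragment,
)
from .fragmentation import FragmentLibrary
from .policy import (
    TransformerParams,
    actor_forward,
    critic_forward,
    sample_action,
)
from .rewards import (
    ActivityClassifier,
    PropertyRanges,
    RewardWeights,
    total_reward,
)
from .tree import FragmentTree

logger = logging.getLogger(__name__)

__all__ = ["Transition", "Trajectory", "TrainConfig", "TimeSchedule",
           "run_episode", "advantage", "a2c_update", "train", "generate"]


@dataclass
class Transition:
    state: MoleculeState
    action: tuple[int, int]
    reward: float
    next_state: MoleculeState
    value_estimate: float
    done: bool
    valid: bool
    gate_pass: bool
    property_reward: float


@dataclass
class Trajectory:
    transitions: list[Transition]
    episode_seed: int
    initial_source: str


@dataclass
class TimeSchedule:
    """Fixed Time, or stepped up when the gate-pass moving average plateaus."""

    mode: str = "fixed"                 # "fixed" | "plateau"
    max_time: int = 6
    window: int = 50
    tolerance: float = 0.01

    def update(self, time: int, gate_history: list[float]) -> int:
        if self.mode != "plateau" or time >= self.max_time:
            return time
        if len(gate_history) < 2 * self.window:
            return time
        recent = float(np.mean(gate_history[-self.window:]))
        earlier = float(np.mean(gate_history[-2 * self.window:-self.window]))
        if recent - earlier < self.tolerance:
            return time + 1
        return time


@dataclass
class TrainConfig:
    gamma: float = 0.99
    lr_actor: float = 3e-4
    lr_critic: float = 3e-4
    entropy_coef: float = 0.01
    time: int = 1
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    use_property_optimization: bool = True
    ranges: PropertyRanges = field(default_factory=PropertyRanges)
    weights: RewardWeights = field(default_factory=RewardWeights)
    time_schedule: TimeSchedule = field(default_factory=TimeSchedule)

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.time < 1:
            raise ValueError("Time must be >= 1")


def advantage(reward: float, value: float, next_value: float,
              gamma: float, done: bool) -> float:
    """One-step TD advantage: r + gamma * V(s') * (1 - done) - V(s)."""
    return reward + gamma * next_value * (1.0 - float(done)) - value


def _step_reward(cfg: TrainConfig, smiles: str,
                 classifier: ActivityClassifier | None = None,
                 feats=None):
    return total_reward(
        smiles,
        ranges=cfg.ranges,
        weights=cfg.weights,
        classifier=classifier,
        feats=feats,
        use_property_optimization=cfg.use_property_optimization,
    )


def run_episode(
    initial: MoleculeState,
    params: TransformerParams,
    tree: FragmentTree,
    lib: FragmentLibrary,
    cfg: TrainConfig,
    rng: np.random.Generator,
    classifier: ActivityClassifier | None = None,
    score_fn=None,
) -> Trajectory:
    """Exactly ``cfg.time`` replacement steps; invalid steps revert.

    ``score_fn(smiles) -> DockingFeatures`` hooks docking-based activity
    reward in when configured.
    """
    episode_seed = int(rng.integers(2**31 - 1))
    ep_rng = np.random.default_rng(episode_seed)
    state = initial
    transitions: list[Transition] = []
    for t in range(cfg.time):
        dist = actor_forward(state, tree, params, lib)
        action = sample_action(dist, ep_rng)
        value = critic_forward(state, tree, params).value
        pos, frag = action
        valid = True
        try:
            next_state = replace_fragment(state, pos, frag, lib)
        except AssemblyError:
            valid = False
            next_state = state  # revert to the last valid state
        if valid:
            feats = score_fn(next_state.source) if score_fn else None
            rc = _step_reward(cfg, next_state.source, classifier, feats)
            reward, gate, prop_r = rc.total, rc.gate_pass, rc.property_reward
        else:
            reward, gate, prop_r = 0.0, False, 0.0
        transitions.append(
            Transition(
                state=state,
                action=action,
                reward=reward,
                next_state=next_state,
                value_estimate=value,
                done=(t == cfg.time - 1),
                valid=valid,
                gate_pass=gate,
                property_reward=prop_r,
            )
        )
        state = next_state
    return Trajectory(transitions=transitions, episode_seed=episode_seed,
                      initial_source=initial.source)


def a2c_update(
    batch: list[Trajectory],
    params: TransformerParams,
    tree: FragmentTree,
    lib: FragmentLibrary,
    cfg: TrainConfig,
    optimizer,
) -> dict:
    """One synchronous gradient step on actor and critic losses."""
    if not batch:
        raise ValueError("empty batch")
    actor_terms = []
    critic_terms = []
    entropy_terms = []
    for traj in batch:
        for tr in traj.transitions:
            dist = actor_forward(tr.state, tree, params, lib)
            v = critic_forward(tr.state, tree, params)
            next_v = 0.0 if tr.done else critic_forward(
                tr.next_state, tree, params).value
            adv = advantage(tr.reward, v.value, next_v, cfg.gamma, tr.done)
            logp = dist.log_prob(*tr.action)
            actor_terms.append(logp * float(adv))
            target = tr.reward + cfg.gamma * next_v * (1.0 - float(tr.done))
            critic_terms.append((v.tensor - float(target)) ** 2.0)
            entropy_terms.append(dist.entropy())
    n = float(len(actor_terms))
    actor_loss = -(sum(actor_terms[1:], actor_terms[0]) / n) \
        - cfg.entropy_coef * (sum(entropy_terms[1:], entropy_terms[0]) / n)
    critic_loss = sum(critic_terms[1:], critic_terms[0]) / n
    loss = actor_loss + critic_loss
    optimizer.zero_grad()
    loss.backward()
    try:
        optimizer.step()
    except FloatingPointError as exc:
        raise FloatingPointError(f"NaN/Inf gradient during A2C update: {exc}") from exc
    return {
        "actor_loss": float(actor_loss.data),
        "critic_loss": float(critic_loss.data),
    }


def train(
    seed_molecules: list[str],
    lib: FragmentLibrary,
    tree: FragmentTree,
    cfg: TrainConfig,
    params: TransformerParams | None = None,
    classifier: ActivityClassifier | None = None,
    score_fn=None,
    log_path: str | None = None,
) -> tuple[TransformerParams, list[dict]]:
    """Epochs of batched episodes with per-epoch validity / gate-pass logging."""
    if not seed_molecules:
        raise ValueError("empty seed molecule set")
    states = [decompose(s, lib, frozen=True) for s in seed_molecules]
    if params is None:
        params = TransformerParams(
            lib_size=len(lib), code_len=tree.code_length, seed=cfg.seed
        )
    optimizer = params.make_optimizer(cfg.lr_actor, cfg.lr_critic)
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    gate_history: list[float] = []
    time_now = cfg.time
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            epoch_cfg = TrainConfig(**{**cfg.__dict__, "time": time_now})
            batch = []
            for _ in range(cfg.batch_size):
                init = states[int(rng.integers(len(states)))]
                batch.append(
                    run_episode(init, params, tree, lib, epoch_cfg, rng,
                                classifier=classifier, score_fn=score_fn)
                )
            losses = a2c_update(batch, params, tree, lib, epoch_cfg, optimizer)
            steps = [tr for traj in batch for tr in traj.transitions]
            record = {
                "epoch": epoch,
                "time": time_now,
                "valid_fraction": float(np.mean([tr.valid for tr in steps])),
                "gate_pass_fraction": float(np.mean([tr.gate_pass for tr in steps])),
                "mean_reward": float(np.mean([tr.reward for tr in steps])),
                "property_reward": float(np.mean([tr.property_reward for tr in steps])),
                **losses,
            }
            gate_history.append(record["gate_pass_fraction"])
            time_now = cfg.time_schedule.update(time_now, gate_history)
            log.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if epoch % max(1, cfg.epochs // 10) == 0:
                logger.info("epoch %d: %s", epoch, record)
    finally:
        if log_fh:
            log_fh.close()
    return params, log


def generate(
    params: TransformerParams,
    seed_molecules: list[str],
    lib: FragmentLibrary,
    tree: FragmentTree,
    n: int,
    time: int,
    rng: np.random.Generator,
) -> list[str]:
    """Final molecules of ``n`` greedy-sampled episodes (possibly invalid).

    Each episode applies ``time`` sampled replacements.  A step whose
    replacement cannot be assembled keeps the previous state but the attempted
    (invalid) structure is what the episode reports if it was the last step,
    so validity statistics reflect what the policy actually proposed.
    """
    states = [decompose(s, lib, frozen=True) for s in seed_molecules]
    out: list[str] = []
    for _ in range(n):
        state = states[int(rng.integers(len(states)))]
        last_attempt = state.source
        for _t in range(time):
            dist = actor_forward(state, tree, params, lib)
            pos, frag = sample_action(dist, rng)
            try:
                rewired = rewire_fragment(state, pos, frag, lib)
            except IncompatibleFragmentError:
                last_attempt = ""  # masked action slipped through; count invalid
                continue
            try:
                state = replace_fragment(state, pos, frag, lib)
                last_attempt = state.source
            except AssemblyError:
                # keep the previous valid state; report the failed attempt
                last_attempt = assemble_raw(rewired, lib)
        out.append(last_attempt)
    return out
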