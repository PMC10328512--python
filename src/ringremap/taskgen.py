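"""Task generation: path integration on a circular track plus latent-state inference.

The task couples two classic problems. A network receives per-step angular
velocities for each spatial dimension of a periodic (circular or toroidal)
environment and must integrate them to report position as (sin, cos) pairs.
At the same time it receives transient one-hot cue pulses announcing switches
of a discrete latent state ("context"), and must report the currently active
state persistently between pulses.

All randomness flows through a single :class:`numpy.random.Generator`, so a
fixed seed reproduces every batch bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

TWO_PI = 2.0 * np.pi

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the navigation + latent-state-inference task.

    Parameters
    ----------
    spatial_dims : int
        Number of periodic spatial dimensions, 1 (ring) or 2 (torus).
    n_states : int
        Number of discrete latent states K (>= 2).
    vel_noise_sd : float
        Per-step velocity noise standard deviation, radians/step.
    mean_vel_sd : float
        Standard deviation of the per-sequence mean velocity, radians/step.
    cue_rate : float
        Expected latent-state switches per time step (homogeneous Poisson).
    cue_pulse_len : int
        Duration of each state-cue pulse in steps.
    seq_len : int
        Sequence length T.
    batch_size : int
        Number of sequences B sampled per batch.
    eval_mode : bool
        Evaluation regime: nonnegative velocity (speed = |mean + noise|) and
        initial position fixed at 0, producing a trialized session with
        repeated track traversals.
    seed : int, optional
        Convenience seed; :meth:`make_rng` builds a generator from it.
    """

    spatial_dims: int = 1
    n_states: int = 2
    vel_noise_sd: float = 0.3
    mean_vel_sd: float = 0.1
    cue_rate: float = 1.0 / 50.0
    cue_pulse_len: int = 2
    seq_len: int = 600
    batch_size: int = 124
    eval_mode: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.spatial_dims not in (1, 2):
            raise ValueError(f"spatial_dims must be 1 or 2, got {self.spatial_dims}")
        if self.n_states < 2:
            raise ValueError(f"n_states must be >= 2, got {self.n_states}")
        if self.vel_noise_sd < 0 or self.mean_vel_sd < 0:
            raise ValueError("velocity standard deviations must be nonnegative")
        if self.cue_rate < 0:
            raise ValueError("cue_rate must be nonnegative")
        if self.cue_pulse_len < 1:
            raise ValueError("cue_pulse_len must be >= 1")
        if self.seq_len < 1 or self.batch_size < 1:
            raise ValueError("seq_len and batch_size must be positive")

    # Input/output widths implied by the task.
    @property
    def n_inputs(self) -> int:
        """M = spatial_dims + n_states (velocity channels, then cue channels)."""
        return self.spatial_dims + self.n_states

    @property
    def n_outputs(self) -> int:
        """L = 2*spatial_dims + n_states ((sin, cos) per dim, then state logits)."""
        return 2 * self.spatial_dims + self.n_states

    @property
    def n_init_inputs(self) -> int:
        """M0 = 2*spatial_dims ((sin, cos) of the initial position per dim)."""
        return 2 * self.spatial_dims

    def make_rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def eval_variant(config: TaskConfig, cue_rate: float = 1.0 / 500.0,
                 seq_len: int | None = None) -> TaskConfig:
    """Evaluation-regime copy of ``config``: nonnegative velocity, rarer cues."""
    return replace(
        config,
        eval_mode=True,
        cue_rate=cue_rate,
        seq_len=config.seq_len if seq_len is None else seq_len,
        batch_size=1,
    )


@dataclass
class SequenceBatch:
    """One sampled batch of task sequences.

    ``inputs`` has shape (T, B, M) with velocity channels first and the K cue
    channels after them. ``pos_target`` holds (sin, cos) per spatial dimension,
    interleaved as [sin_0, cos_0, sin_1, cos_1, ...]. ``angle`` is the ground
    truth position in [0, 2*pi) per dimension.
    """

    inputs: np.ndarray        # (T, B, M)
    pos_target: np.ndarray    # (T, B, 2D)
    state_target: np.ndarray  # (T, B) int
    init_input: np.ndarray    # (B, 2D)
    angle: np.ndarray         # (T, B, D)
    config: TaskConfig

    @property
    def seq_len(self) -> int:
        return self.inputs.shape[0]

    @property
    def batch_size(self) -> int:
        return self.inputs.shape[1]

    def cue_mask(self) -> np.ndarray:
        """Boolean (T, B): steps during which any cue channel is active."""
        d = self.config.spatial_dims
        return (self.inputs[:, :, d:] > 0).any(axis=2)

    def truncated(self, length: int) -> "SequenceBatch":
        """Copy keeping only the first ``length`` time steps."""
        return SequenceBatch(
            inputs=self.inputs[:length],
            pos_target=self.pos_target[:length],
            state_target=self.state_target[:length],
            init_input=self.init_input,
            angle=self.angle[:length],
            config=self.config,
        )


def sample_velocity(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample per-step angular velocities, shape (T, B, D).

    Each sequence (and each spatial dimension independently) draws a mean
    velocity ~ Normal(0, mean_vel_sd); per-step velocities are that mean plus
    Normal(0, vel_noise_sd) noise. In eval mode the speed is the absolute
    value, so the track is traversed in one direction.
    """
    t, b, d = config.seq_len, config.batch_size, config.spatial_dims
    mean_vel = rng.normal(0.0, config.mean_vel_sd, size=(1, b, d))
    noise = rng.normal(0.0, config.vel_noise_sd, size=(t, b, d))
    vel = mean_vel + noise
    if config.eval_mode:
        vel = np.abs(vel)
    return vel


def sample_state_track(config: TaskConfig, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sample cue pulses and the latent-state track.

    Returns ``(cues, states)`` with shapes (T, B, K) and (T, B). Switch times
    follow a homogeneous Poisson process at ``cue_rate`` events/step; at each
    switch one of the K-1 inactive states is chosen uniformly and its channel
    emits a pulse of 1s lasting ``cue_pulse_len`` steps. The initial state is
    uniform over K and is itself cued by a pulse at t=0 so that it is always
    observable. An event landing inside an active pulse is deferred to the
    step after that pulse ends, keeping pulses well formed.
    """
    t, b, k = config.seq_len, config.batch_size, config.n_states
    cues = np.zeros((t, b, k), dtype=float)
    states = np.zeros((t, b), dtype=np.int64)
    plen = config.cue_pulse_len
    for j in range(b):
        state = int(rng.integers(k))
        states[:, j] = state
        cues[0:plen, j, state] = 1.0
        if config.cue_rate <= 0:
            continue
        next_free = plen
        clock = rng.exponential(1.0 / config.cue_rate)
        while True:
            onset = int(np.floor(clock))
            if onset >= t:
                break
            onset = max(onset, next_free)  # defer events inside a pulse
            if onset >= t:
                break
            others = [s for s in range(k) if s != state]
            state = int(others[rng.integers(k - 1)])
            cues[onset:onset + plen, j, state] = 1.0
            states[onset:, j] = state
            next_free = onset + plen
            clock = max(clock, float(onset)) + rng.exponential(1.0 / config.cue_rate)
    return cues, states


def encode_angle(angle: np.ndarray) -> np.ndarray:
    """Encode angles (..., D) as interleaved (sin, cos) pairs (..., 2D)."""
    out = np.empty(angle.shape[:-1] + (2 * angle.shape[-1],), dtype=float)
    out[..., 0::2] = np.sin(angle)
    out[..., 1::2] = np.cos(angle)
    return out


def decode_angle(sincos: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_angle`; angles wrapped to [0, 2*pi)."""
    return np.mod(np.arctan2(sincos[..., 0::2], sincos[..., 1::2]), TWO_PI)


def sample_batch(config: TaskConfig, rng: np.random.Generator) -> SequenceBatch:
    """Sample a full input/target batch.

    The initial angle is uniform on [0, 2*pi) per dimension (0 in eval mode);
    angles integrate the sampled velocities and wrap periodically.
    """
    t, b, d = config.seq_len, config.batch_size, config.spatial_dims
    vel = sample_velocity(config, rng)
    cues, states = sample_state_track(config, rng)
    if config.eval_mode:
        theta0 = np.zeros((b, d))
    else:
        theta0 = rng.uniform(0.0, TWO_PI, size=(b, d))
    unwrapped = theta0[None] + np.cumsum(vel, axis=0)
    angle = np.mod(unwrapped, TWO_PI)
    inputs = np.concatenate([vel, cues], axis=2)
    return SequenceBatch(
        inputs=inputs,
        pos_target=encode_angle(angle),
        state_target=states,
        init_input=encode_angle(theta0),
        angle=angle,
        config=config,
    )


@dataclass
class EvalStream:
    """Concatenated evaluation session inputs with ground truth.

    ``sequences`` are independently sampled eval-mode batches (batch size 1),
    each truncated to complete track traversals. ``boundaries`` index the
    concatenated time axis; each (start, stop) pair is one complete traversal.
    """

    sequences: list[SequenceBatch]
    angle: np.ndarray              # (T_total,)
    state: np.ndarray              # (T_total,) int
    boundaries: list[tuple[int, int]]
    config: TaskConfig

    @property
    def total_steps(self) -> int:
        return self.angle.shape[0]


def _traversal_spans(unwrapped: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """Complete-traversal spans of a nonnegative unwrapped trajectory from 0.

    A traversal is complete once cumulative position has advanced by a further
    2*pi; the sample landing exactly on a multiple of 2*pi closes a traversal.
    Returns (n_steps_kept, spans relative to the sequence start).
    """
    n_complete = int(np.floor(unwrapped[-1] / TWO_PI))
    if n_complete == 0:
        return 0, []
    spans = []
    for lap in range(n_complete):
        start = int(np.searchsorted(unwrapped, lap * TWO_PI, side="right"))
        stop = int(np.searchsorted(unwrapped, (lap + 1) * TWO_PI, side="right"))
        spans.append((start, stop))
    return spans[-1][1], spans


def build_eval_session(config: TaskConfig, n_sequences: int = 50,
                       rng: np.random.Generator | None = None) -> EvalStream:
    """Sample an evaluation session of concatenated, truncated sequences.

    Each of ``n_sequences`` eval-mode sequences is truncated to its complete
    track traversals (trailing partial laps dropped); sequences with no
    complete traversal are dropped with a logged warning. Only 1D tracks are
    trialized this way.
    """
    if not config.eval_mode:
        raise ValueError("build_eval_session requires an eval_mode TaskConfig")
    if config.spatial_dims != 1:
        raise NotImplementedError("trialized eval sessions are defined for 1D tracks")
    if rng is None:
        rng = config.make_rng()
    cfg = replace(config, batch_size=1)
    sequences: list[SequenceBatch] = []
    angles, states_all, boundaries = [], [], []
    offset = 0
    for i in range(n_sequences):
        batch = sample_batch(cfg, rng)
        vel = batch.inputs[:, 0, 0]
        unwrapped = np.cumsum(vel)
        keep, spans = _traversal_spans(unwrapped)
        if keep == 0:
            log.warning("eval sequence %d has no complete traversal; dropped", i)
            continue
        trunc = batch.truncated(keep)
        sequences.append(trunc)
        angles.append(trunc.angle[:, 0, 0])
        states_all.append(trunc.state_target[:, 0])
        boundaries.extend((offset + s, offset + e) for s, e in spans)
        offset += keep
    if not sequences:
        raise RuntimeError("no eval sequence contained a complete traversal")
    return EvalStream(
        sequences=sequences,
        angle=np.concatenate(angles),
        state=np.concatenate(states_all),
        boundaries=boundaries,
        config=cfg,
    )


def save_batch(path, batch: SequenceBatch) -> None:
    """Serialize a batch as a compressed .npz plus the config in JSON."""
    import json
    from dataclasses import asdict

    np.savez_compressed(
        path,
        inputs=batch.inputs, pos_target=batch.pos_target,
        state_target=batch.state_target, init_input=batch.init_input,
        angle=batch.angle,
        config=np.frombuffer(json.dumps(asdict(batch.config)).encode(), dtype=np.uint8),
    )


def load_batch(path) -> SequenceBatch:
    import json

    with np.load(path) as f:
        cfg = TaskConfig(**json.loads(bytes(f["config"]).decode()))
        return SequenceBatch(
            inputs=f["inputs"], pos_target=f["pos_target"],
            state_target=f["state_target"], init_input=f["init_input"],
            angle=f["angle"], config=cfg,
        )
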