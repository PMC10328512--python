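"""Elman recurrent network as a discrete-time dynamical system.

The hidden state updates as ``x_{t+1} = ReLU(A x_t + B u_t + beta)`` with a
linear readout ``y_t = C x_t + alpha`` and a learned linear initial-condition
encoder ``x_0 = D z + gamma``, where z encodes the starting position as
(sin, cos) pairs. All parameters live in plain NumPy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .taskgen import TWO_PI, SequenceBatch, TaskConfig


class DivergenceError(RuntimeError):
    """Raised when the hidden state becomes non-finite during a rollout."""

    def __init__(self, step: int):
        super().__init__(f"hidden state diverged (NaN/Inf) at step {step}")
        self.step = step


@dataclass
class RNNParams:
    """The seven trainable parameter groups {A, B, beta, C, alpha, D, gamma}."""

    A: np.ndarray       # (N, N) recurrent weights
    B: np.ndarray       # (N, M) input weights
    beta: np.ndarray    # (N,) hidden bias
    C: np.ndarray       # (L, N) readout weights
    alpha: np.ndarray   # (L,) readout bias
    D: np.ndarray       # (N, M0) init-encoder weights
    gamma: np.ndarray   # (N,) init-encoder bias

    @property
    def n_units(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    @property
    def n_init_inputs(self) -> int:
        return self.D.shape[1]

    def position_readout(self, spatial_dims: int = 1) -> np.ndarray:
        """The (2D, N) readout rows decoding (sin, cos) of position — the
        matrix W whose nullspace hosts decoder-invisible remapping."""
        return self.C[: 2 * spatial_dims]

    def copy(self) -> "RNNParams":
        return RNNParams(*(getattr(self, f).copy() for f in _FIELDS))

    def astuple(self):
        return tuple(getattr(self, f) for f in _FIELDS)


_FIELDS = ("A", "B", "beta", "C", "alpha", "D", "gamma")


def init_params(n_units: int, n_inputs: int, n_outputs: int, n_init_inputs: int,
                rng: np.random.Generator) -> RNNParams:
    """Initialize all parameter groups i.i.d. Uniform(-1/sqrt(N), 1/sqrt(N))."""
    if min(n_units, n_inputs, n_outputs, n_init_inputs) < 1:
        raise ValueError("all dimensions must be positive")
    bound = 1.0 / np.sqrt(n_units)

    def u(*shape):
        return rng.uniform(-bound, bound, size=shape)

    return RNNParams(
        A=u(n_units, n_units),
        B=u(n_units, n_inputs),
        beta=u(n_units),
        C=u(n_outputs, n_units),
        alpha=u(n_outputs),
        D=u(n_units, n_init_inputs),
        gamma=u(n_units),
    )


def init_for_task(config: TaskConfig, n_units: int,
                  rng: np.random.Generator) -> RNNParams:
    return init_params(n_units, config.n_inputs, config.n_outputs,
                       config.n_init_inputs, rng)


def step(params: RNNParams, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One update ``ReLU(A x + B u + beta)``; accepts (N,)/(M,) or batched rows."""
    if x.shape[-1] != params.n_units or u.shape[-1] != params.n_inputs:
        raise ValueError(
            f"shape mismatch: x{x.shape}, u{u.shape} vs N={params.n_units}, "
            f"M={params.n_inputs}")
    pre = x @ params.A.T + u @ params.B.T + params.beta
    return np.maximum(pre, 0.0)


def encode_init(params: RNNParams, z: np.ndarray) -> np.ndarray:
    """Initial condition ``x_0 = D z + gamma`` (linear, not rectified)."""
    return z @ params.D.T + params.gamma


@dataclass
class ForwardTrace:
    """Hidden states and outputs of one rollout.

    ``hidden`` is (T, B, N) and nonnegative; ``outputs`` is (T, B, L) with the
    first 2D entries the (sin, cos) position prediction and the last K the
    state logits.
    """

    hidden: np.ndarray
    outputs: np.ndarray
    spatial_dims: int
    n_states: int


def forward(params: RNNParams, batch: SequenceBatch) -> ForwardTrace:
    """Roll the network over a batch; raises :class:`DivergenceError` on NaN."""
    x0, hidden = _rollout(params, batch)
    outputs = hidden @ params.C.T + params.alpha
    return ForwardTrace(hidden=hidden, outputs=outputs,
                        spatial_dims=batch.config.spatial_dims,
                        n_states=batch.config.n_states)


def _rollout(params: RNNParams, batch: SequenceBatch
             ) -> tuple[np.ndarray, np.ndarray]:
    """Internal rollout returning (x0, hidden); used by forward and training."""
    t_len, b = batch.seq_len, batch.batch_size
    x = encode_init(params, batch.init_input)
    x0 = x
    hidden = np.empty((t_len, b, params.n_units))
    for t in range(t_len):
        x = step(params, x, batch.inputs[t])
        if not np.all(np.isfinite(x)):
            raise DivergenceError(t)
        hidden[t] = x
    return x0, hidden


def decode_position(trace: ForwardTrace) -> np.ndarray:
    """Predicted angles (T, B, D) via atan2 of the (sin, cos) readout."""
    twod = 2 * trace.spatial_dims
    y = trace.outputs[..., :twod]
    return np.mod(np.arctan2(y[..., 0::2], y[..., 1::2]), TWO_PI)


def decode_state(trace: ForwardTrace) -> np.ndarray:
    """Predicted latent-state labels (T, B) via argmax of the logits."""
    return np.argmax(trace.outputs[..., 2 * trace.spatial_dims:], axis=-1)


def save_checkpoint(path, params: RNNParams, config: TaskConfig | None = None,
                    metadata: dict | None = None) -> None:
    """Write the seven parameter groups to .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, A=params.A, B=params.B, beta=params.beta,
                        C=params.C, alpha=params.alpha, D=params.D,
                        gamma=params.gamma)
    meta = dict(metadata or {})
    meta["n_units"] = params.n_units
    if config is not None:
        from dataclasses import asdict
        meta["task_config"] = asdict(config)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[RNNParams, dict]:
    path = Path(path)
    with np.load(path) as f:
        params = RNNParams(A=f["A"], B=f["B"], beta=f["beta"], C=f["C"],
                           alpha=f["alpha"], D=f["D"], gamma=f["gamma"])
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return params, meta
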