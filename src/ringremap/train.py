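"""Curriculum training of the recurrent network.

The loss is the sum of (i) the mean-squared error of the (sin, cos) position
prediction and (ii) the mean per-step cross-entropy of the state logits
against the true latent state. Optimization is stochastic gradient descent
with global gradient-norm clipping; sequences start at length 1 and grow by
one step every ``curriculum_step`` parameter updates up to ``max_seq_len``.
Gradients are computed by explicit backpropagation through time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import model as mod
from .taskgen import TWO_PI, SequenceBatch, TaskConfig, sample_batch

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    n_updates: int = 30000
    batch_size: int = 124
    clip_norm: float = 2.0
    curriculum_step: int = 50
    max_seq_len: int = 600
    learning_rate: float = 0.05
    final_learning_rate: float | None = None  # linear decay target; None = constant
    momentum: float = 0.0
    optimizer: str = "sgd"      # "sgd" | "adam"
    log_every: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_updates, self.batch_size, self.curriculum_step,
               self.max_seq_len) < 0 or self.batch_size == 0:
            raise ValueError("training sizes must be positive")
        if self.clip_norm <= 0 or self.learning_rate <= 0:
            raise ValueError("clip_norm and learning_rate must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


def curriculum_length(update_index: int, config: TrainConfig) -> int:
    """Sequence length for parameter update ``update_index`` (0-based):
    T = min(1 + floor(k / curriculum_step), max_seq_len)."""
    if update_index < 0:
        raise ValueError("update_index must be >= 0")
    return min(1 + update_index // config.curriculum_step, config.max_seq_len)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def loss(trace: mod.ForwardTrace, batch: SequenceBatch
         ) -> tuple[float, float, float]:
    """(position MSE, state cross-entropy, total) for a forward trace.

    The MSE averages over time, batch and the 2D sin/cos channels; the
    cross-entropy averages -log softmax(logits)[true state] over time and
    batch. Total is their unweighted sum.
    """
    twod = 2 * trace.spatial_dims
    pos_err = trace.outputs[..., :twod] - batch.pos_target
    pos_mse = float(np.mean(pos_err ** 2))
    logits = trace.outputs[..., twod:]
    logp = logits - logits.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    t, b = batch.seq_len, batch.batch_size
    picked = np.take_along_axis(logp, batch.state_target[..., None], axis=-1)
    state_ce = float(-picked.mean())
    return pos_mse, state_ce, pos_mse + state_ce


def loss_and_grads(params: mod.RNNParams, batch: SequenceBatch
                   ) -> tuple[float, float, dict[str, np.ndarray]]:
    """Forward pass, loss, and exact gradients via backprop through time."""
    x0, X = mod._rollout(params, batch)
    Y = X @ params.C.T + params.alpha
    t_len, b = batch.seq_len, batch.batch_size
    twod = 2 * batch.config.spatial_dims

    pos_err = Y[..., :twod] - batch.pos_target
    pos_mse = float(np.mean(pos_err ** 2))
    p = _softmax(Y[..., twod:])
    picked = np.take_along_axis(p, batch.state_target[..., None], axis=-1)
    state_ce = float(-np.log(np.clip(picked, 1e-300, None)).mean())

    dY = np.empty_like(Y)
    dY[..., :twod] = 2.0 * pos_err / pos_err.size
    dlogits = p.copy()
    np.put_along_axis(
        dlogits, batch.state_target[..., None],
        np.take_along_axis(dlogits, batch.state_target[..., None], axis=-1) - 1.0,
        axis=-1)
    dY[..., twod:] = dlogits / (t_len * b)

    grads = {
        "C": np.einsum("tbl,tbn->ln", dY, X),
        "alpha": dY.sum(axis=(0, 1)),
        "A": np.zeros_like(params.A),
        "B": np.zeros_like(params.B),
        "beta": np.zeros_like(params.beta),
    }
    dX = dY @ params.C
    carry = np.zeros((b, params.n_units))
    for t in range(t_len - 1, -1, -1):
        delta = (dX[t] + carry) * (X[t] > 0)
        xprev = X[t - 1] if t > 0 else x0
        grads["A"] += delta.T @ xprev
        grads["B"] += delta.T @ batch.inputs[t]
        grads["beta"] += delta.sum(axis=0)
        carry = delta @ params.A
    grads["D"] = carry.T @ batch.init_input
    grads["gamma"] = carry.sum(axis=0)
    return pos_mse, state_ce, grads


def clip_gradients(grads: dict[str, np.ndarray], clip_norm: float
                   ) -> tuple[dict[str, np.ndarray], float]:
    """Scale the whole gradient so its global L2 norm is <= clip_norm.

    Returns the (possibly rescaled) gradients and the post-clip norm.
    """
    total = float(np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values())))
    if total > clip_norm:
        scale = clip_norm / total
        grads = {k: g * scale for k, g in grads.items()}
        return grads, clip_norm
    return grads, total


def train(params: mod.RNNParams, task_config: TaskConfig,
          train_config: TrainConfig, rng: np.random.Generator | None = None
          ) -> tuple[mod.RNNParams, pd.DataFrame]:
    """Run the curriculum training loop.

    Returns the trained parameters and a per-update log (seq_len, position
    loss, state loss, total, post-clip gradient norm). On a non-finite loss
    the loop aborts, returning the parameters from the last good update.
    """
    if rng is None:
        rng = np.random.default_rng(train_config.seed)
    params = params.copy()
    velocity = {f: np.zeros_like(getattr(params, f)) for f in mod._FIELDS}
    second = {f: np.zeros_like(getattr(params, f)) for f in mod._FIELDS}
    rows = []
    prev = params.copy()
    for k in range(train_config.n_updates):
        t_len = curriculum_length(k, train_config)
        cfg = replace(task_config, seq_len=t_len,
                      batch_size=train_config.batch_size)
        batch = sample_batch(cfg, rng)
        try:
            pos_mse, state_ce, grads = loss_and_grads(params, batch)
        except mod.DivergenceError:
            log.error("training diverged at update %d; keeping last good "
                      "parameters", k)
            return prev, pd.DataFrame(rows)
        if not np.isfinite(pos_mse + state_ce):
            log.error("non-finite loss at update %d; keeping last good "
                      "parameters", k)
            return prev, pd.DataFrame(rows)
        grads, gnorm = clip_gradients(grads, train_config.clip_norm)
        prev = params.copy()
        lr = train_config.learning_rate
        if train_config.final_learning_rate is not None:
            frac = k / max(train_config.n_updates - 1, 1)
            lr = lr + frac * (train_config.final_learning_rate - lr)
        if train_config.optimizer == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            for f in mod._FIELDS:
                velocity[f] = b1 * velocity[f] + (1 - b1) * grads[f]
                second[f] = b2 * second[f] + (1 - b2) * grads[f] ** 2
                mh = velocity[f] / (1 - b1 ** (k + 1))
                vh = second[f] / (1 - b2 ** (k + 1))
                getattr(params, f)[...] -= lr * mh / (np.sqrt(vh) + eps)
        else:
            mom = train_config.momentum
            for f in mod._FIELDS:
                if mom > 0:
                    velocity[f] = mom * velocity[f] + grads[f]
                    upd = velocity[f]
                else:
                    upd = grads[f]
                getattr(params, f)[...] -= lr * upd
        if k % train_config.log_every == 0 or k == train_config.n_updates - 1:
            rows.append(dict(update=k, seq_len=t_len, pos_mse=pos_mse,
                             state_ce=state_ce, total=pos_mse + state_ce,
                             grad_norm=gnorm))
    return params, pd.DataFrame(rows)


def evaluate(params: mod.RNNParams, task_config: TaskConfig,
             n_episodes: int = 50, horizon: int = 300,
             rng: np.random.Generator | None = None
             ) -> tuple[float, float]:
    """Held-out performance: state accuracy and angular error at ``horizon``.

    Simulates ``n_episodes`` fresh sequences of length ``horizon`` with the
    task's training statistics. State accuracy is the fraction of steps,
    excluding cue-pulse steps (the state is transitioning while a pulse is
    on), where the argmax-decoded state matches the truth. The angular error
    is the circular absolute difference between decoded and true position at
    t = horizon, in degrees, averaged over episodes (and spatial dims).
    """
    if rng is None:
        rng = np.random.default_rng()
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    cfg = replace(task_config, seq_len=horizon, batch_size=n_episodes,
                  eval_mode=False)
    batch = sample_batch(cfg, rng)
    trace = mod.forward(params, batch)
    decoded = mod.decode_state(trace)
    keep = ~batch.cue_mask()
    acc = float((decoded == batch.state_target)[keep].mean())
    ang = mod.decode_position(trace)[-1]          # (B, D)
    diff = np.abs(ang - batch.angle[-1])
    diff = np.minimum(diff, TWO_PI - diff)
    err_deg = float(np.degrees(diff).mean())
    return acc, err_deg
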