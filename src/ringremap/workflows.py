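"""End-to-end experiment recipes shared by tests and scripts.

The full-scale experiment (N=248 units, 30,000 updates, sequences growing to
T=600) takes hours on one CPU. The reduced configuration defined here —
N=64 units, 5,000 updates, sequences growing to T=150 — reaches the same
qualitative regime (perfect state inference, aligned ring manifolds, saddle
mediated remapping) in a few minutes and is the configuration the package's
own analyses and tests run at.
"""

from __future__ import annotations

import numpy as np

from . import dynamics as dyn
from . import geometry as geo
from . import model as mod
from . import session as ses
from .taskgen import TaskConfig, build_eval_session, eval_variant
from .train import TrainConfig, train

SCALED_N_UNITS = 64


def scaled_task_config(n_states: int = 2, spatial_dims: int = 1) -> TaskConfig:
    """Task statistics are identical at every scale; only sizes shrink."""
    return TaskConfig(spatial_dims=spatial_dims, n_states=n_states)


def scaled_train_config(seed: int | None = None) -> TrainConfig:
    """Reduced-scale training recipe.

    Adam with a linearly decayed step size; the batch size, gradient
    clipping and +1-step-per-50-updates curriculum match the full-scale
    procedure, with the length capped at 150 (so the ramp spans most of
    training) and 5,000 updates.
    """
    return TrainConfig(
        n_updates=5000,
        batch_size=124,
        clip_norm=2.0,
        curriculum_step=33,
        max_seq_len=150,
        learning_rate=5e-3,
        final_learning_rate=2e-4,
        optimizer="adam",
        seed=seed,
    )


def train_scaled_model(n_states: int = 2, seed: int = 0,
                       n_units: int = SCALED_N_UNITS,
                       train_config: TrainConfig | None = None
                       ) -> tuple[mod.RNNParams, TaskConfig]:
    """Train one reduced-scale model; returns (params, task_config)."""
    task = scaled_task_config(n_states=n_states)
    tc = train_config or scaled_train_config(seed=seed)
    rng = np.random.default_rng(seed)
    params = mod.init_for_task(task, n_units, rng)
    params, _ = train(params, task, tc, rng)
    return params, task


def collect_eval_session(params: mod.RNNParams, task: TaskConfig,
                         seed: int = 0, n_sequences: int = 50,
                         seq_len: int = 500) -> ses.Session:
    """Standard evaluation session: rare cues, nonnegative velocity."""
    cfg = eval_variant(task, seq_len=seq_len)
    stream = build_eval_session(cfg, n_sequences=n_sequences,
                                rng=np.random.default_rng(seed))
    return ses.collect_session(params, stream)


def two_map_geometry(params: mod.RNNParams, session: ses.Session,
                     seed: int = 0, n_shuffle: int = 300) -> dict:
    """The standard two-map geometry battery for one trained model.

    Returns the 50-bin manifolds, Procrustes misalignment, remapping-vector
    analysis against the position readout W, the across-map position
    subspace (250 bins), and the remapping dimension.
    """
    rng = np.random.default_rng(seed)
    tuning50 = ses.map_tuning(session, n_bins=50)
    tuning250 = ses.map_tuning(session, n_bins=250)
    w = params.position_readout(spatial_dims=1)
    mis = geo.procrustes_misalignment(tuning50.tuning[0], tuning50.tuning[1],
                                      n_shuffle=n_shuffle, rng=rng)
    remap = geo.remap_vectors(tuning50, w, n_shuffle=n_shuffle, rng=rng)
    pos_basis = geo.position_subspace(tuning250, scope="across")
    remap_dim = geo.remap_dimension(tuning250, 0, 1)
    return dict(tuning50=tuning50, tuning250=tuning250,
                misalignment=mis, remap=remap, pos_basis=pos_basis,
                remap_dim=remap_dim, W=w)


def fixed_point_analysis(params: mod.RNNParams, session: ses.Session,
                         tuning: ses.MapTuning, seed: int = 0,
                         n_seeds: int = 1024, tol: float = 1e-6
                         ) -> dyn.FixedPointSet:
    """Locate, linearize, classify and coordinate the fixed points."""
    rng = np.random.default_rng(seed)
    seeds = dyn.seed_states(session, n_seeds, rng)
    fps = dyn.find_fixed_points(params, seeds, tol=tol)
    if fps.n_points:
        dyn.linearize(params, fps)
        dyn.classify_all(fps)
        c1, c2 = tuning.centroid(0), tuning.centroid(1)
        fps.remap_coords = dyn.remap_coordinate(fps.points, c1, c2)
    return fps
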