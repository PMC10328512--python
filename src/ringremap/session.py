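"""Trialized session analysis: binning, map labels, stability, unit scores.

A :class:`Session` is a continuous evaluation run (hidden activity plus
ground-truth position/state) cut into complete track traversals. Traversals
are averaged into position bins to give per-trial rate maps, labeled by the
predominant latent state or by k-means clustering of their spatial firing
patterns, filtered for trial-to-trial stability, and summarized per map as
tuning curves (the empirical manifolds). The operations accept generic
trials x bins x units tensors, so they apply equally to recorded data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans

from . import model as mod
from .taskgen import TWO_PI, EvalStream

log = logging.getLogger(__name__)


@dataclass
class Session:
    """A continuous run with ground truth and traversal boundaries."""

    activity: np.ndarray   # (T_total, N)
    angle: np.ndarray      # (T_total,)
    state: np.ndarray      # (T_total,) int
    boundaries: list[tuple[int, int]]
    source: str = "rnn"    # "rnn" | "synthetic-fixture"


@dataclass
class TrialSet:
    """Position-binned trials: rates (R, P, N) with per-trial map labels."""

    rates: np.ndarray      # (R, P, N)
    labels: np.ndarray     # (R,) int
    n_bins: int

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    def flat(self) -> np.ndarray:
        """Trials as flattened (R, P*N) vectors."""
        return self.rates.reshape(self.n_trials, -1)


@dataclass
class MapTuning:
    """Per-map position-binned mean activations, shape (n_maps, P, N)."""

    tuning: np.ndarray
    bin_centers: np.ndarray
    maps: np.ndarray       # map identities, (n_maps,)

    @property
    def n_maps(self) -> int:
        return self.tuning.shape[0]

    def centroid(self, m: int) -> np.ndarray:
        """Mean activity vector of map ``m`` over position bins."""
        return self.tuning[m].mean(axis=0)


def collect_session(params: mod.RNNParams, stream: EvalStream) -> Session:
    """Run the model over each eval sequence and concatenate hidden states."""
    parts = []
    for seq in stream.sequences:
        trace = mod.forward(params, seq)
        parts.append(trace.hidden[:, 0, :])
    return Session(activity=np.concatenate(parts, axis=0),
                   angle=stream.angle, state=stream.state,
                   boundaries=stream.boundaries, source="rnn")


def _bin_index(angle: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(angle / TWO_PI * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _fill_circular(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill missing bins by linear interpolation on the circle (per column)."""
    p = values.shape[0]
    known = ~missing
    if known.sum() == 0:
        return np.zeros_like(values)
    idx = np.arange(p)
    kidx = idx[known]
    # unwrap the circular domain by tiling known bins on both sides
    xs = np.concatenate([kidx - p, kidx, kidx + p])
    out = values.copy()
    for c in range(values.shape[1]):
        ys = np.tile(values[known, c], 3)
        out[missing, c] = np.interp(idx[missing], xs, ys)
    return out


def _majority_label(states: np.ndarray) -> int:
    """Predominant state; ties break toward the state active earlier."""
    vals, first, counts = np.unique(states, return_index=True,
                                    return_counts=True)
    best = counts == counts.max()
    cand_first = first[best]
    return int(vals[best][np.argmin(cand_first)])


def trialize(session: Session, n_bins: int = 50) -> TrialSet:
    """Average activity within position bins for each complete traversal.

    Each traversal becomes one trial of shape (n_bins, N); bins a traversal
    never visited are filled by circular linear interpolation from their
    neighbors. Trials are labeled by the predominant latent state.
    """
    trials, labels = [], []
    n_short = 0
    for (start, stop) in session.boundaries:
        if stop - start < n_bins:
            n_short += 1
        idx = _bin_index(session.angle[start:stop], n_bins)
        act = session.activity[start:stop]
        sums = np.zeros((n_bins, act.shape[1]))
        counts = np.zeros(n_bins)
        np.add.at(sums, idx, act)
        np.add.at(counts, idx, 1)
        missing = counts == 0
        with np.errstate(invalid="ignore"):
            rates = sums / counts[:, None]
        rates = _fill_circular(np.where(missing[:, None], 0.0, rates), missing)
        trials.append(rates)
        labels.append(_majority_label(session.state[start:stop]))
    if n_short:
        log.warning("%d/%d traversals have fewer samples than bins (%d); "
                    "their empty bins were interpolated",
                    n_short, len(session.boundaries), n_bins)
    return TrialSet(rates=np.asarray(trials), labels=np.asarray(labels),
                    n_bins=n_bins)


def map_tuning(session: Session, n_bins: int = 250,
               states: np.ndarray | None = None) -> MapTuning:
    """Per-map tuning curves pooling all time samples by (state, position bin).

    Empty bins within a map are filled by circular interpolation. ``states``
    selects/orders the maps (default: all states present, sorted).
    """
    if states is None:
        states = np.unique(session.state)
    idx = _bin_index(session.angle, n_bins)
    n = session.activity.shape[1]
    tuning = np.zeros((len(states), n_bins, n))
    for k, s in enumerate(states):
        sel = session.state == s
        sums = np.zeros((n_bins, n))
        counts = np.zeros(n_bins)
        np.add.at(sums, idx[sel], session.activity[sel])
        np.add.at(counts, idx[sel], 1)
        missing = counts == 0
        with np.errstate(invalid="ignore"):
            t = np.where(missing[:, None], 0.0, sums / counts[:, None])
        tuning[k] = _fill_circular(t, missing)
    centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    return MapTuning(tuning=tuning, bin_centers=centers,
                     maps=np.asarray(states))


def tuning_from_trials(trials: TrialSet, labels: np.ndarray | None = None
                       ) -> MapTuning:
    """Map tuning as the mean binned rate over same-label trials."""
    labels = trials.labels if labels is None else np.asarray(labels)
    maps = np.unique(labels)
    tuning = np.stack([trials.rates[labels == m].mean(axis=0) for m in maps])
    centers = (np.arange(trials.n_bins) + 0.5) * TWO_PI / trials.n_bins
    return MapTuning(tuning=tuning, bin_centers=centers, maps=maps)


def trial_corr_matrix(trials: TrialSet) -> np.ndarray:
    """Pearson correlations between flattened trial rate vectors.

    Entry (i, j) correlates the bins x units vectors of trials i and j;
    the diagonal is exactly 1. A zero-variance trial gets correlation 0
    with everything (with a warning), by convention.
    """
    x = trials.flat()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance trial(s); correlations set to 0",
                    int(degenerate.sum()))
    xc = x - x.mean(axis=1, keepdims=True)
    safe_sd = np.where(degenerate, 1.0, sd)
    corr = (xc @ xc.T) / (x.shape[1] * np.outer(safe_sd, safe_sd))
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def kmeans_maps(trials: TrialSet, k: int, seed: int = 0, n_init: int = 10
                ) -> tuple[np.ndarray, np.ndarray]:
    """k-means map assignment of trials by their spatial firing patterns.

    Returns per-trial labels and the cluster centroids reshaped to
    (k, P, N) — the centroids double as manifold estimates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > trials.n_trials:
        raise ValueError(f"k={k} exceeds number of trials {trials.n_trials}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(trials.flat())
    centroids = km.cluster_centers_.reshape(k, trials.n_bins, -1)
    return labels, centroids


def stability_filter(trials: TrialSet, labels: np.ndarray,
                     threshold: float = 0.25) -> np.ndarray:
    """Indices of spatially stable trials.

    Within each map, a trial is dropped when its mean correlation with all
    other trials of the same map falls below ``threshold``.
    """
    labels = np.asarray(labels)
    corr = trial_corr_matrix(trials)
    keep = []
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        if idx.size == 1:
            keep.extend(idx)  # nothing to compare against
            continue
        sub = corr[np.ix_(idx, idx)]
        mean_other = (sub.sum(axis=1) - 1.0) / (idx.size - 1)
        kept = idx[mean_other >= threshold]
        if kept.size == 0:
            log.warning("map %s lost all trials to the stability filter", m)
        keep.extend(kept)
    return np.sort(np.asarray(keep, dtype=int))


def single_unit_scores(tuning: MapTuning, smooth_sd_bins: float = 2.0
                       ) -> pd.DataFrame:
    """Per-unit remapping scores between exactly two maps.

    Tuning curves are Gaussian-smoothed on the circle (sd in bins), then:

    - ``rate_remap_pct``: percent change in peak rate,
      |peak1 - peak2| / max(peak1, peak2) * 100 (rate remapping);
    - ``spatial_dissim``: 1 - cosine similarity of the two curves, in [0, 2]
      (global remapping).

    A unit silent in both maps gets (0, 0) and ``degenerate=True``.
    """
    if tuning.n_maps != 2:
        raise ValueError("single_unit_scores needs exactly two maps")
    sm = gaussian_filter1d(tuning.tuning, smooth_sd_bins, axis=1, mode="wrap")
    c1, c2 = sm[0], sm[1]                    # (P, N)
    peak1, peak2 = c1.max(axis=0), c2.max(axis=0)
    peak_hi = np.maximum(peak1, peak2)
    degenerate = peak_hi <= 0
    safe_hi = np.where(degenerate, 1.0, peak_hi)
    rate_pct = np.abs(peak1 - peak2) / safe_hi * 100.0
    n1 = np.linalg.norm(c1, axis=0)
    n2 = np.linalg.norm(c2, axis=0)
    zero_norm = (n1 == 0) | (n2 == 0)
    cos = np.where(zero_norm, 1.0,
                   (c1 * c2).sum(axis=0) / np.where(zero_norm, 1.0, n1 * n2))
    dissim = 1.0 - cos
    rate_pct[degenerate] = 0.0
    dissim[degenerate | zero_norm] = 0.0
    return pd.DataFrame(dict(unit=np.arange(c1.shape[1]),
                             rate_remap_pct=rate_pct,
                             spatial_dissim=dissim,
                             degenerate=degenerate | zero_norm))


def export_trial_table(trials: TrialSet, labels: np.ndarray,
                       kept: np.ndarray, path) -> None:
    """CSV of per-trial map assignment and stability outcome."""
    corr = trial_corr_matrix(trials)
    mean_corr = (corr.sum(axis=1) - 1.0) / max(trials.n_trials - 1, 1)
    df = pd.DataFrame(dict(trial_id=np.arange(trials.n_trials),
                           map=np.asarray(labels),
                           kept=np.isin(np.arange(trials.n_trials), kept),
                           corr_mean=mean_corr))
    df.to_csv(path, index=False)
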