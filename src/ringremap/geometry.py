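"""Population-geometry analyses of the learned spatial maps.

Given per-map position-binned tuning (the empirical ring/torus manifolds),
this module measures how the maps relate in the N-dimensional activity
space: Procrustes misalignment against a random-rotation null, remapping
vectors and their structure inside the nullspace of the position readout,
position subspaces and remapping dimensions, cosine similarities of weight
vectors to those subspaces, and multi-map remapping-dimension angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import null_space
from scipy.stats import ortho_group, special_ortho_group

from .session import MapTuning


# ---------------------------------------------------------------------------
# PCA spectra

def pca_variance(data: np.ndarray) -> np.ndarray:
    """Cumulative fraction of variance explained by the principal components.

    ``data`` is (samples, units); rows are mean-centered. The curve is
    nondecreasing and ends at 1.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D array with at least 2 samples")
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return np.ones(min(x.shape))
    return np.cumsum(var) / total


# ---------------------------------------------------------------------------
# Procrustes misalignment

@dataclass
class MisalignmentResult:
    """Observed vs optimal-rotation RMSE, a rotation null, and the score.

    ``score`` is 0 when the manifolds are already optimally aligned and 1
    when the observed misalignment reaches the reference quantile (default
    p=0.25) of the random-rotation null. ``null_rmse`` holds the full null
    so alternative normalizations (e.g. the null mean) can be read off.
    """

    rmse_observed: float
    rmse_optimal: float
    null_rmse: np.ndarray
    score: float
    rotation: np.ndarray
    null_quantile: float

    @property
    def score_vs_null_mean(self) -> float:
        """Alternative normalization using the null mean as the 1 point."""
        denom = self.null_rmse.mean() - self.rmse_optimal
        return (self.rmse_observed - self.rmse_optimal) / denom


def _center_scale(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    norm = np.linalg.norm(xc)
    if norm == 0:
        raise ValueError("degenerate manifold with zero variance")
    return xc / norm


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def best_rotation(a: np.ndarray, b: np.ndarray,
                  rotation_only: bool = True) -> np.ndarray:
    """Orthogonal matrix R minimizing ||a - b R||_F (Kabsch/Procrustes).

    With ``rotation_only`` the solution is constrained to det(R) = +1
    (a proper rotation, no reflection).
    """
    u, _, vt = np.linalg.svd(b.T @ a)
    if rotation_only:
        d = np.sign(np.linalg.det(u @ vt))
        u[:, -1] *= d
    return u @ vt


def procrustes_misalignment(tuning_a: np.ndarray, tuning_b: np.ndarray,
                            n_shuffle: int = 1000,
                            rng: np.random.Generator | None = None,
                            quantile: float = 0.25,
                            rotation_only: bool = True) -> MisalignmentResult:
    """Normalized Procrustes misalignment between two (P, N) manifolds.

    Both manifolds are mean-centered and rescaled to unit Frobenius norm.
    The observed RMSE between them is compared with (i) the RMSE after the
    optimal rotation of b onto a and (ii) a null of RMSEs after random
    orthogonal rotations of b (Haar measure), and reported as

        score = (rmse_obs - rmse_opt) / (null_quantile - rmse_opt).
    """
    a, b = np.asarray(tuning_a, float), np.asarray(tuning_b, float)
    if a.shape != b.shape:
        raise ValueError("manifolds must share (P, N) shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 position bins for shape analysis")
    if rng is None:
        rng = np.random.default_rng()
    a, b = _center_scale(a), _center_scale(b)
    rmse_obs = _rmse(a, b)
    rot = best_rotation(a, b, rotation_only=rotation_only)
    rmse_opt = _rmse(a, b @ rot)
    n = a.shape[1]
    sampler = special_ortho_group if rotation_only else ortho_group
    qs = sampler.rvs(n, size=n_shuffle, random_state=rng)
    if n_shuffle == 1:
        qs = qs[None]
    null = np.array([_rmse(a, b @ q) for q in qs])
    q_null = float(np.quantile(null, quantile))
    denom = q_null - rmse_opt
    score = (rmse_obs - rmse_opt) / denom if denom > 0 else np.inf
    return MisalignmentResult(rmse_observed=rmse_obs, rmse_optimal=rmse_opt,
                              null_rmse=null, score=float(score),
                              rotation=rot, null_quantile=quantile)


# ---------------------------------------------------------------------------
# Remapping vectors and the nullspace of the position readout

@dataclass
class RemapAnalysis:
    """Structure of the remapping vectors xi_p = x_p(2) - x_p(1).

    ``ideal`` is their mean v; ``deviation`` is the per-bin normalized
    departure ||xi_p - v|| / <||xi_p||>. ``w_residual`` holds |W xi_p| per
    bin (near zero when both maps decode position identically). Two nulls
    accompany them: deviations after rotating map 2 about its centroid
    within the nullspace of W (decoding-preserving misalignment), and W
    residuals after unrestricted random rotation of map 2 (which breaks the
    shared decoder).
    """

    xi: np.ndarray              # (P, N)
    ideal: np.ndarray           # (N,)
    deviation: np.ndarray       # (P,)
    w_residual: np.ndarray      # (P,)
    null_deviation: np.ndarray  # (n_shuffle, P)
    null_w_residual: np.ndarray  # (n_shuffle, P)
    variance_spectrum: np.ndarray  # cumulative, from PCA of centered xi


def _deviation(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = xi.mean(axis=0)
    scale = np.linalg.norm(xi, axis=1).mean()
    return v, np.linalg.norm(xi - v, axis=1) / scale


def remap_vectors(tuning: MapTuning, W: np.ndarray, n_shuffle: int = 1000,
                  rng: np.random.Generator | None = None) -> RemapAnalysis:
    """Empirical remapping vectors between two maps and their nulls.

    ``W`` is the (2D, N) position-readout submatrix. The nullspace-rotation
    null rotates the centered map 2 by Z O Z^T + (I - Z Z^T) with Z an
    orthonormal basis of null(W) and O Haar-orthogonal: this preserves
    W x for every point, i.e. it explores exactly the decoder-compatible
    misalignments. The W-residual null instead applies unrestricted random
    rotations about the map-2 centroid.
    """
    if tuning.n_maps != 2:
        raise ValueError("remap_vectors needs exactly two maps")
    if rng is None:
        rng = np.random.default_rng()
    x1, x2 = tuning.tuning[0], tuning.tuning[1]
    xi = x2 - x1
    v, dev = _deviation(xi)
    w_res = np.linalg.norm(xi @ W.T, axis=1)

    n = x1.shape[1]
    z = null_space(W)                      # (N, N - 2D)
    c2 = x2.mean(axis=0)
    b = x2 - c2
    p_keep = np.eye(n) - z @ z.T           # projector onto row space of W
    null_dev = np.empty((n_shuffle, xi.shape[0]))
    null_wres = np.empty((n_shuffle, xi.shape[0]))
    k = z.shape[1]
    for i in range(n_shuffle):
        o = special_ortho_group.rvs(k, random_state=rng)
        r_null = z @ o @ z.T + p_keep
        xi_null = (c2 + b @ r_null.T) - x1
        _, null_dev[i] = _deviation(xi_null)
        r_full = special_ortho_group.rvs(n, random_state=rng)
        xi_full = (c2 + b @ r_full.T) - x1
        null_wres[i] = np.linalg.norm(xi_full @ W.T, axis=1)
    spectrum = pca_variance(xi) if xi.shape[0] >= 2 else np.ones(1)
    return RemapAnalysis(xi=xi, ideal=v, deviation=dev, w_residual=w_res,
                         null_deviation=null_dev, null_w_residual=null_wres,
                         variance_spectrum=spectrum)


# ---------------------------------------------------------------------------
# Subspaces

def position_subspace(tuning: MapTuning, scope: str = "across",
                      map_index: int | None = None) -> np.ndarray:
    """Orthonormal (N, 2) basis of the position subspace.

    Top-2 principal axes of the mean-centered position-binned activity:
    with ``scope='across'`` every map is first centered on its own centroid
    and the bins of all maps are concatenated (one shared plane, with the
    between-map translation removed so the plane is purely positional);
    with ``scope='per-map'`` only ``map_index`` is used.
    """
    if scope == "across":
        centered = tuning.tuning - tuning.tuning.mean(axis=1, keepdims=True)
        data = centered.reshape(-1, tuning.tuning.shape[2])
    elif scope == "per-map":
        if map_index is None:
            raise ValueError("map_index required for scope='per-map'")
        data = tuning.tuning[map_index]
    else:
        raise ValueError("scope must be 'across' or 'per-map'")
    xc = data - data.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[:2].T


def remap_dimension(tuning: MapTuning, i: int, j: int) -> np.ndarray:
    """Unit vector from map i's centroid to map j's centroid."""
    if i == j:
        raise ValueError("need two distinct maps")
    d = tuning.centroid(j) - tuning.centroid(i)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("identical map centroids; remapping dimension "
                         "undefined")
    return d / norm


def cosine_to_subspace(vector: np.ndarray, basis: np.ndarray) -> float:
    """|projection| / |vector| onto the span of ``basis`` columns, in [0, 1].

    ``basis`` may be a single vector (angle cosine) or an orthonormal
    (N, k) matrix; 1 means the vector lies inside the subspace, 0 means
    orthogonal to it.
    """
    v = np.asarray(vector, float).ravel()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    b = np.asarray(basis, float)
    if b.ndim == 1:
        b = b[:, None]
    q, _ = np.linalg.qr(b)
    return float(np.linalg.norm(q.T @ v) / norm)


def subspace_alignment(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Cosine of the smallest principal angle between two subspaces."""
    qa, _ = np.linalg.qr(np.atleast_2d(basis_a.T).T)
    qb, _ = np.linalg.qr(np.atleast_2d(basis_b.T).T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.clip(s.max(), 0.0, 1.0))


def random_cosine_null(basis: np.ndarray, n_samples: int = 10000,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Cosines of isotropic random unit vectors to a fixed subspace."""
    if rng is None:
        rng = np.random.default_rng()
    b = np.asarray(basis, float)
    if b.ndim == 1:
        b = b[:, None]
    n = b.shape[0]
    v = rng.standard_normal((n_samples, n))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    q, _ = np.linalg.qr(b)
    return np.linalg.norm(v @ q, axis=1)


def remap_dim_angles(tuning: MapTuning
                     ) -> dict[tuple[tuple[int, int], tuple[int, int]], float]:
    """Pairwise acute angles (degrees) between remapping dimensions.

    Requires at least 3 maps. Keys are pairs of map pairs, e.g.
    ``((0, 1), (0, 2))``; values are arccos(|cos|) in [0, 90].
    """
    if tuning.n_maps < 3:
        raise ValueError("need at least 3 maps for pairwise remap angles")
    pairs = list(combinations(range(tuning.n_maps), 2))
    dims = {p: remap_dimension(tuning, *p) for p in pairs}
    out = {}
    for (pa, pb) in combinations(pairs, 2):
        c = abs(float(dims[pa] @ dims[pb]))
        out[(pa, pb)] = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return out


def torus_slices(tuning_2d: np.ndarray, axis: str, level: int) -> np.ndarray:
    """Extract a 1D ring from 2D (Px, Py, N) binned tuning.

    ``axis='x'`` holds the X bin fixed at ``level`` and returns the ring
    over Y (shape (Py, N)); ``axis='y'`` the converse. Downstream ring
    analyses (PCA, Procrustes) apply to the slice unchanged.
    """
    t = np.asarray(tuning_2d)
    if t.ndim != 3:
        raise ValueError("expected (Px, Py, N) tuning")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    size = t.shape[0] if axis == "x" else t.shape[1]
    if not 0 <= level < size:
        raise ValueError(f"level {level} out of range for axis {axis!r}")
    return t[level] if axis == "x" else t[:, level]
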