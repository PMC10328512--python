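"""Fixed points and local linear dynamics of the trained network.

With zero input the network is an autonomous map ``x -> ReLU(A x + beta)``.
Approximate fixed points are located by minimizing ``0.5 ||x - ReLU(A x +
beta)||^2`` from many seed states, deduplicated, and linearized: the
Jacobian at a fixed point is A with the rows of inactive units zeroed.
Points are classified by spectral radius into marginally stable ring points
(integrator directions, |lambda_max| ~ 1), unstable saddles that funnel
activity between ring attractors, and strictly contracting points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import RNNParams
from .session import Session

log = logging.getLogger(__name__)

MARGINAL = "marginally-stable"
UNSTABLE = "unstable"
OTHER = "other"


@dataclass
class FixedPointSet:
    """Located fixed points with spectra, classes, and remap coordinates."""

    points: np.ndarray       # (F, N)
    residuals: np.ndarray    # (F,) ||x - ReLU(Ax + beta)||
    eigenvalues: np.ndarray | None = None   # (F, N) complex
    classes: np.ndarray | None = None       # (F,) str
    remap_coords: np.ndarray | None = None  # (F,)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def select(self, mask: np.ndarray) -> "FixedPointSet":
        def take(a):
            return None if a is None else a[mask]
        return FixedPointSet(self.points[mask], self.residuals[mask],
                             take(self.eigenvalues), take(self.classes),
                             take(self.remap_coords))


def save_fixed_points(path, fps: FixedPointSet) -> None:
    """Store a fixed-point set as .npz (eigenvalues split re/im) + CSV."""
    import pandas as pd

    arrays = dict(points=fps.points, residuals=fps.residuals)
    if fps.eigenvalues is not None:
        arrays["eig_real"] = fps.eigenvalues.real
        arrays["eig_imag"] = fps.eigenvalues.imag
    if fps.classes is not None:
        arrays["classes"] = fps.classes.astype("U")
    if fps.remap_coords is not None:
        arrays["remap_coords"] = fps.remap_coords
    np.savez_compressed(path, **arrays)
    rows = dict(point=np.arange(fps.n_points), residual=fps.residuals)
    if fps.eigenvalues is not None:
        rows["spectral_radius"] = np.abs(fps.eigenvalues).max(axis=1)
    if fps.classes is not None:
        rows["class"] = fps.classes
    if fps.remap_coords is not None:
        rows["remap_coord"] = fps.remap_coords
    pd.DataFrame(rows).to_csv(str(path) + ".csv", index=False)


def load_fixed_points(path) -> FixedPointSet:
    with np.load(path) as f:
        eig = (f["eig_real"] + 1j * f["eig_imag"]
               if "eig_real" in f else None)
        return FixedPointSet(
            points=f["points"], residuals=f["residuals"], eigenvalues=eig,
            classes=f["classes"] if "classes" in f else None,
            remap_coords=f["remap_coords"] if "remap_coords" in f else None)


def zero_input_map(params: RNNParams, x: np.ndarray) -> np.ndarray:
    """One autonomous step ReLU(A x + beta); batched over leading axes."""
    return np.maximum(x @ params.A.T + params.beta, 0.0)


def residual_norm(params: RNNParams, x: np.ndarray) -> np.ndarray:
    """||x - ReLU(A x + beta)|| per point (batched)."""
    return np.linalg.norm(x - zero_input_map(params, x), axis=-1)


def _objective_grad(params: RNNParams, x: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Value and gradient of q(x) = 0.5 ||x - ReLU(Ax + beta)||^2, batched."""
    pre = x @ params.A.T + params.beta
    r = np.maximum(pre, 0.0)
    e = x - r
    q = 0.5 * np.sum(e ** 2, axis=-1)
    grad = e - (e * (pre > 0)) @ params.A
    return q, grad


def seed_states(sessions: Session | list[Session], n_seeds: int,
                rng: np.random.Generator, noise_sd: float = 0.1,
                mixture_frac: float = 0.5) -> np.ndarray:
    """Draw optimization seeds from visited states plus cross-state mixtures.

    Half the seeds (by default) are visited hidden states with isotropic
    Gaussian noise; the rest are convex mixtures of state pairs drawn from
    different maps, which populate the region between the ring manifolds
    where the intermediate (saddle) fixed points live.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    acts = np.concatenate([s.activity for s in sessions])
    states = np.concatenate([s.state for s in sessions])
    n_mix = int(round(n_seeds * mixture_frac))
    n_on = n_seeds - n_mix
    idx = rng.integers(acts.shape[0], size=n_on)
    seeds = [acts[idx] + rng.normal(0, noise_sd, (n_on, acts.shape[1]))]
    labels = np.unique(states)
    if n_mix > 0 and labels.size >= 2:
        pairs = rng.choice(labels.size, size=(n_mix, 2))
        pairs[pairs[:, 0] == pairs[:, 1], 1] = (
            pairs[pairs[:, 0] == pairs[:, 1], 0] + 1) % labels.size
        lam = rng.uniform(0.2, 0.8, size=(n_mix, 1))
        a_idx = np.array([rng.choice(np.flatnonzero(states == labels[i]))
                          for i in pairs[:, 0]])
        b_idx = np.array([rng.choice(np.flatnonzero(states == labels[j]))
                          for j in pairs[:, 1]])
        mix = lam * acts[a_idx] + (1 - lam) * acts[b_idx]
        seeds.append(mix + rng.normal(0, noise_sd, mix.shape))
    elif n_mix > 0:
        idx = rng.integers(acts.shape[0], size=n_mix)
        seeds.append(acts[idx] + rng.normal(0, noise_sd, (n_mix, acts.shape[1])))
    return np.concatenate(seeds)


def dedup_points(points: np.ndarray, merge_radius: float = 0.01
                 ) -> np.ndarray:
    """Greedy deduplication: indices of representatives spaced > radius."""
    keep: list[int] = []
    for i, p in enumerate(points):
        if all(np.linalg.norm(p - points[j]) > merge_radius for j in keep):
            keep.append(i)
    return np.asarray(keep, dtype=int)


def find_fixed_points(params: RNNParams, seeds: np.ndarray,
                      tol: float = 1e-6, merge_radius: float = 0.01,
                      n_iter: int = 2000, lr: float = 0.05,
                      polish: bool = True) -> FixedPointSet:
    """Locate approximate fixed points of the zero-input dynamics.

    All seeds are optimized in parallel with Adam on the squared-residual
    objective; survivors are deduplicated and (optionally) polished with
    L-BFGS-B to push residuals below ``tol``. Points whose final residual
    exceeds ``tol`` are discarded; an empty result logs a warning.
    """
    x = np.asarray(seeds, float).copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, n_iter + 1):
        _, g = _objective_grad(params, x)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g ** 2
        mh = m / (1 - b1 ** t)
        vh = v / (1 - b2 ** t)
        # linear step-size decay sharpens convergence near the minima
        x -= lr * (1.0 - 0.9 * t / n_iter) * mh / (np.sqrt(vh) + eps)
    res = residual_norm(params, x)
    # generous shortlist: the polish stage does the final convergence work
    shortlist = res < (1e-2 if polish else tol)
    x, res = x[shortlist], res[shortlist]
    order = np.argsort(res)
    x, res = x[order], res[order]
    # light pre-dedup only to avoid polishing near-duplicates
    keep = dedup_points(x, 0.5 * merge_radius)
    x, res = x[keep], res[keep]
    if polish and x.size:
        def fun(xi):
            q, g = _objective_grad(params, xi)
            return float(q), g
        polished = []
        for xi in x:
            out = minimize(fun, xi, jac=True, method="L-BFGS-B",
                           options=dict(maxiter=500, ftol=1e-18, gtol=1e-14))
            polished.append(out.x)
        x = np.asarray(polished)
        res = residual_norm(params, x)
    good = res < tol
    x, res = x[good], res[good]
    if x.size:
        keep = dedup_points(x, merge_radius)
        x, res = x[keep], res[keep]
    if x.size == 0:
        log.warning("no fixed point converged below tol=%g", tol)
    return FixedPointSet(points=x.reshape(-1, params.n_units), residuals=res)


def jacobian_at(params: RNNParams, x_star: np.ndarray) -> np.ndarray:
    """Jacobian of the zero-input map at ``x_star``.

    For the rectified-linear update this is A with row i zeroed whenever
    unit i's pre-activation is <= 0 (pre-activation exactly 0 counts as
    inactive, the subgradient-0 convention).
    """
    pre = params.A @ x_star + params.beta
    return (pre > 0)[:, None] * params.A


def linearize(params: RNNParams, fps: FixedPointSet) -> FixedPointSet:
    """Attach Jacobian eigen-decompositions; stores eigenvalues in place."""
    n = params.n_units
    eigvals = np.empty((fps.n_points, n), dtype=complex)
    for i, x in enumerate(fps.points):
        eigvals[i] = np.linalg.eigvals(jacobian_at(params, x))
    fps.eigenvalues = eigvals
    return fps


def classify(eigenvalues: np.ndarray,
             cutoffs: tuple[float, float] = (0.95, 1.05)) -> str:
    """Class from the spectral radius rho = max |lambda|.

    marginally-stable if rho in [lo, hi]; unstable if rho > hi; other
    (strictly contracting) if rho < lo.
    """
    lo, hi = cutoffs
    rho = float(np.abs(eigenvalues).max())
    if rho > hi:
        return UNSTABLE
    if rho >= lo:
        return MARGINAL
    return OTHER


def classify_all(fps: FixedPointSet,
                 cutoffs: tuple[float, float] = (0.95, 1.05)) -> FixedPointSet:
    if fps.eigenvalues is None:
        raise ValueError("linearize the fixed points first")
    fps.classes = np.array([classify(ev, cutoffs) for ev in fps.eigenvalues])
    return fps


def remap_coordinate(x_star: np.ndarray, c1: np.ndarray, c2: np.ndarray
                     ) -> float | np.ndarray:
    """Signed position along the remapping axis: c1 -> -1, c2 -> +1, mid -> 0.

    Components of x orthogonal to (c2 - c1) do not contribute.
    """
    d = c2 - c1
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("identical centroids; remap coordinate undefined")
    mid = 0.5 * (c1 + c2)
    return 2.0 * ((x_star - mid) @ d) / denom


def principal_eigenvector_basis(params: RNNParams, x_star: np.ndarray
                                ) -> np.ndarray:
    """Orthonormal basis for the principal eigendirection at a fixed point.

    Real principal eigenvalue: a single column. Complex: the 2D real
    invariant subspace spanned by the real and imaginary parts.
    """
    jac = jacobian_at(params, x_star)
    w, vecs = np.linalg.eig(jac)
    i = int(np.argmax(np.abs(w)))
    vec = vecs[:, i]
    if np.abs(w[i].imag) > 1e-12:
        basis = np.stack([vec.real, vec.imag], axis=1)
    else:
        basis = vec.real[:, None]
    q, _ = np.linalg.qr(basis)
    return q


def eigvec_alignment(params: RNNParams, fps: FixedPointSet,
                     remap_dim: np.ndarray, pos_bases: list[np.ndarray],
                     coords: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cosines of each principal eigenvector to the remapping dimension and
    to the position subspace of the nearer map.

    ``pos_bases`` holds per-map (N, 2) bases ordered [map1, map2]; the
    nearer map is chosen by the sign of the remap coordinate (``coords``
    defaults to ``fps.remap_coords``). For a complex principal pair, the
    cosine uses the smallest principal angle of its 2D real span.
    """
    from .geometry import subspace_alignment

    if coords is None:
        coords = fps.remap_coords
    if coords is None:
        raise ValueError("remap coordinates required to pick the nearer map")
    cos_remap = np.empty(fps.n_points)
    cos_pos = np.empty(fps.n_points)
    for i, x in enumerate(fps.points):
        basis = principal_eigenvector_basis(params, x)
        cos_remap[i] = subspace_alignment(basis, remap_dim[:, None])
        near = 0 if coords[i] < 0 else 1
        cos_pos[i] = subspace_alignment(basis, pos_bases[near])
    return cos_remap, cos_pos


def iterate(params: RNNParams, x0: np.ndarray, n_steps: int) -> np.ndarray:
    """Iterate the zero-input map; returns the trajectory (n_steps+1, N)."""
    traj = np.empty((n_steps + 1,) + x0.shape)
    traj[0] = x0
    x = x0
    for t in range(n_steps):
        x = zero_input_map(params, x)
        traj[t + 1] = x
    return traj


def funnel_endpoints(params: RNNParams, saddle: np.ndarray,
                     eps: float = 0.1, n_steps: int = 200
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of trajectories seeded +/- eps along the principal
    eigendirection of a saddle; a funnel sends them to the two attractors."""
    basis = principal_eigenvector_basis(params, saddle)
    direction = basis[:, 0]
    up = iterate(params, saddle + eps * direction, n_steps)[-1]
    dn = iterate(params, saddle - eps * direction, n_steps)[-1]
    return up, dn
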