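"""The five fuzzy clustering solvers: FCM, KFCM, SFCM, SKFCM and MSKFCM.

All solvers share the same structure: alternate a membership update and a
centroid update on the scalar intensity values of the in-mask voxels until
the max-norm centroid change drops to ``epsilon`` or ``max_iter`` is hit.

* FCM   — classic fuzzy c-means (Euclidean distance on intensities).
* KFCM  — kernelized memberships/centroids; distance ``1 - K(x, v)``.
* SFCM  — FCM memberships reweighted by a spatial function ``h`` (the sum
          of neighbors' memberships) via ``u' ∝ u^p h^q``.
* SKFCM — kernelized updates with an additive neighborhood penalty term
          weighted by ``alpha``; the penalty window excludes the center.
* MSKFCM — kernelized memberships reweighted spatially like SFCM, with a
          kernelized centroid update: the combination of KFCM and SFCM.

Spatial sums only ever reference in-bounds, in-mask voxels: windows are
truncated at volume edges and the per-voxel neighbor count ``N_R`` is the
actual count, so no padding or edge replication occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    ClusterParams,
    ClusterState,
    ImageVolume,
    KernelSpec,
    MembershipMatrix,
    NeighborhoodSpec,
    ParameterError,
    kernel_value,
)

__all__ = [
    "InitSpec",
    "SpatialFunction",
    "init_centroids",
    "fcm_memberships",
    "fcm_centroids",
    "run_fcm",
    "kfcm_memberships",
    "kfcm_centroids",
    "run_kfcm",
    "spatial_function",
    "spatial_memberships",
    "run_sfcm",
    "skfcm_memberships",
    "skfcm_centroids",
    "run_skfcm",
    "run_mskfcm",
    "select_nodule_cluster",
    "ALGORITHMS",
]

logger = logging.getLogger(__name__)


class InternalError(RuntimeError):
    """Numerical invariant violated inside a solver (e.g. zero denominator)."""


@dataclass(frozen=True)
class InitSpec:
    """Centroid initialization: operator-provided samples or seeded random.

    In operator mode ``samples`` holds one list per cluster of either raw
    intensities or ``(depth, row, col)`` coordinates; the initial centroid
    of a cluster is the mean intensity of its samples.  Random mode draws
    ``c`` distinct intensities reproducibly from the in-mask range.
    """

    mode: Literal["operator", "random"] = "random"
    samples: tuple[tuple, ...] | None = None
    seed: int = 0


@dataclass
class SpatialFunction:
    """c x n grid ``h[i, j]`` of neighborhood membership sums."""

    values: np.ndarray


def _distinct(centroids: np.ndarray) -> np.ndarray:
    """Perturb duplicate centroids by the smallest representable step."""
    v = np.array(centroids, dtype=np.float64)
    for i in range(len(v)):
        while np.any(v[:i] == v[i]):
            v[i] = v[i] + np.spacing(np.abs(v[i]) + 1.0)
    return v


def init_centroids(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> np.ndarray:
    """Initial centroid intensities, one scalar per cluster."""
    if init.mode == "operator":
        if init.samples is None or len(init.samples) < params.c:
            raise ParameterError(
                f"operator init needs samples for all {params.c} clusters"
            )
        cents = []
        for i in range(params.c):
            samp = init.samples[i]
            if samp is None or len(samp) == 0:
                raise ParameterError(f"empty sample list for cluster {i}")
            vals = []
            for s in samp:
                if np.isscalar(s):
                    vals.append(float(s))
                else:
                    z, r, c = (int(t) for t in s)
                    vals.append(float(volume.voxels[z, r, c]))
            cents.append(float(np.mean(vals)))
        return _distinct(np.array(cents))
    if init.mode == "random":
        x = volume.masked_intensities()
        lo, hi = float(x.min()), float(x.max())
        rng = np.random.default_rng(init.seed)
        cents = rng.uniform(lo, hi, size=params.c) if hi > lo else np.full(params.c, lo)
        return _distinct(cents)
    raise ParameterError(f"unknown init mode {init.mode!r}")


# ---------------------------------------------------------------------------
# membership / centroid updates
# ---------------------------------------------------------------------------


def _normalize_inverse_power(dist: np.ndarray, expo: float) -> np.ndarray:
    """u_ik ∝ dist_ik^(-expo), columns normalized to 1.

    Columns where some ``dist`` vanishes (the voxel coincides with one or
    more centroids in the relevant metric) get a crisp split: membership 1
    shared equally among the vanishing clusters, 0 elsewhere.
    """
    dist = np.asarray(dist, dtype=np.float64)
    zero = dist <= 0.0
    singular = zero.any(axis=0)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(dist > 0, dist, 1.0) ** (-expo)
    u = w / w.sum(axis=0)
    if np.any(singular):
        cols = np.flatnonzero(singular)
        sub = zero[:, cols].astype(np.float64)
        u[:, cols] = sub / sub.sum(axis=0)
    return u


def fcm_memberships(intensities: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update (ratio-of-distances form).

    ``u_ik = [sum_j (|x_k - v_i| / |x_k - v_j|)^(2/(m-1))]^-1``.
    """
    if not m > 1:
        raise ParameterError("fuzzifier m must be > 1")
    x = np.asarray(intensities, dtype=np.float64)
    v = np.asarray(centroids, dtype=np.float64)
    d2 = (x[np.newaxis, :] - v[:, np.newaxis]) ** 2
    return _normalize_inverse_power(d2, 1.0 / (m - 1.0))


def fcm_centroids(intensities: np.ndarray, memberships: np.ndarray, m: float) -> np.ndarray:
    """``v_i = sum_k u_ik^m x_k / sum_k u_ik^m``."""
    x = np.asarray(intensities, dtype=np.float64)
    w = np.asarray(memberships, dtype=np.float64) ** m
    den = w.sum(axis=1)
    if np.any(den <= 0):
        raise InternalError("all-zero membership weight column in centroid update")
    return (w @ x) / den


def kfcm_memberships(
    intensities: np.ndarray, centroids: np.ndarray, m: float, kernel: KernelSpec
) -> np.ndarray:
    """Kernelized membership update: ``u_ik ∝ (1 - K(x_k, v_i))^(-1/(m-1))``."""
    if not m > 1:
        raise ParameterError("fuzzifier m must be > 1")
    x = np.asarray(intensities, dtype=np.float64)
    v = np.asarray(centroids, dtype=np.float64)
    dk = 1.0 - kernel_value(x[np.newaxis, :], v[:, np.newaxis], kernel)
    return _normalize_inverse_power(dk, 1.0 / (m - 1.0))


def kfcm_centroids(
    intensities: np.ndarray,
    centroids_prev: np.ndarray,
    memberships: np.ndarray,
    m: float,
    kernel: KernelSpec,
) -> np.ndarray:
    """``v_i = sum_k u^m K(x_k, v_i) x_k / sum_k u^m K(x_k, v_i)``.

    ``K`` is evaluated against the previous iteration's centroids.
    """
    x = np.asarray(intensities, dtype=np.float64)
    v = np.asarray(centroids_prev, dtype=np.float64)
    K = kernel_value(x[np.newaxis, :], v[:, np.newaxis], kernel)
    w = np.asarray(memberships, dtype=np.float64) ** m * K
    den = w.sum(axis=1)
    if np.any(den <= 0):
        raise InternalError(
            f"vanishing denominator in kernelized centroid update (den={den})"
        )
    return (w @ x) / den


# ---------------------------------------------------------------------------
# spatial machinery
# ---------------------------------------------------------------------------


class _Grid:
    """Scatter/convolve/gather helper for per-voxel neighborhood sums."""

    def __init__(self, volume: ImageVolume, spec: NeighborhoodSpec):
        self.shape = volume.shape
        self.mask = volume.mask_array()
        self.idx = np.flatnonzero(self.mask.reshape(-1))
        self.spec = spec
        self.footprint = spec.footprint()
        # per-voxel count of in-bounds, in-mask window members
        self.n_r = self.neighbor_sum(np.ones(self.idx.size))

    def neighbor_sum(self, field_n: np.ndarray) -> np.ndarray:
        """Sum a per-voxel field over each voxel's window (truncated)."""
        grid = np.zeros(self.shape, dtype=np.float64).reshape(-1)
        grid[self.idx] = field_n
        grid = grid.reshape(self.shape)
        out = ndimage.convolve(grid, self.footprint, mode="constant", cval=0.0)
        return out.reshape(-1)[self.idx]


def spatial_function(
    memberships: np.ndarray, grid: _Grid | None = None, *,
    volume: ImageVolume | None = None, spec: NeighborhoodSpec | None = None,
) -> np.ndarray:
    """Spatial function ``h_ij``: sum of cluster-i memberships over j's window.

    The larger the number of neighbors leaning toward cluster ``i``, the
    larger ``h_ij``.  Accepts a prebuilt :class:`_Grid` or a
    ``volume`` + ``spec`` pair.
    """
    if grid is None:
        if volume is None or spec is None:
            raise ParameterError("spatial_function needs a grid or volume+spec")
        grid = _Grid(volume, spec)
    u = np.asarray(memberships, dtype=np.float64)
    return np.stack([grid.neighbor_sum(u[i]) for i in range(u.shape[0])])


def spatial_memberships(
    memberships: np.ndarray, h: np.ndarray, p: float, q: float
) -> np.ndarray:
    """``u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q``.

    Columns where the normalizer vanishes fall back to the unweighted
    memberships (logged at warning level).
    """
    u = np.asarray(memberships, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if p == 1.0 and q == 0.0:  # exact identity; avoids renormalization noise
        return u.copy()
    with np.errstate(invalid="ignore"):
        num = u**p * h**q
    den = num.sum(axis=0)
    bad = ~(den > 0) | ~np.isfinite(den)
    if np.any(bad):
        logger.warning(
            "spatial membership normalizer vanished at %d voxel(s); "
            "falling back to unweighted memberships there",
            int(bad.sum()),
        )
        num[:, bad] = u[:, bad]
        den = num.sum(axis=0)
    return num / den


# ---------------------------------------------------------------------------
# SKFCM updates (neighborhood penalty, center excluded)
# ---------------------------------------------------------------------------


def _penalty_grid(volume: ImageVolume, spec: NeighborhoodSpec) -> _Grid:
    if spec.include_center:
        raise ParameterError("the SKFCM penalty window must exclude the center")
    return _Grid(volume, spec)


def _skfcm_penalty(dk: np.ndarray, grid: _Grid, alpha: float) -> np.ndarray:
    """(alpha / N_R) * sum over the (center-free) window of a per-voxel field."""
    nbsum = grid.neighbor_sum(dk)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = alpha * nbsum / grid.n_r
    out[grid.n_r == 0] = 0.0  # isolated voxel: no neighbors, no penalty
    return out


def skfcm_memberships(
    intensities: np.ndarray,
    centroids: np.ndarray,
    m: float,
    kernel: KernelSpec,
    grid: _Grid,
    alpha: float,
) -> np.ndarray:
    """Penalized kernelized memberships.

    ``u_ik ∝ [(1 - K(x_k, v_i)) + (alpha/N_R) sum_{r in N_k} (1 - K(x_r, v_i))]^(-1/(m-1))``
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    x = np.asarray(intensities, dtype=np.float64)
    v = np.asarray(centroids, dtype=np.float64)
    dk = 1.0 - kernel_value(x[np.newaxis, :], v[:, np.newaxis], kernel)
    bracket = np.stack([dk[i] + _skfcm_penalty(dk[i], grid, alpha) for i in range(len(v))])
    return _normalize_inverse_power(bracket, 1.0 / (m - 1.0))


def skfcm_centroids(
    intensities: np.ndarray,
    centroids_prev: np.ndarray,
    memberships: np.ndarray,
    m: float,
    kernel: KernelSpec,
    grid: _Grid,
    alpha: float,
) -> np.ndarray:
    """Penalized kernelized centroid update (K against previous centroids)."""
    x = np.asarray(intensities, dtype=np.float64)
    v = np.asarray(centroids_prev, dtype=np.float64)
    um = np.asarray(memberships, dtype=np.float64) ** m
    out = np.empty(len(v))
    for i in range(len(v)):
        Ki = kernel_value(x, v[i], kernel)
        num = um[i] * (Ki * x + _skfcm_penalty(Ki * x, grid, alpha))
        den = um[i] * (Ki + _skfcm_penalty(Ki, grid, alpha))
        dsum = den.sum()
        if not dsum > 0:
            raise InternalError(f"vanishing denominator for cluster {i} in SKFCM centroid update")
        out[i] = num.sum() / dsum
    return out


# ---------------------------------------------------------------------------
# convergence driver
# ---------------------------------------------------------------------------


def _membership_matrix(u: np.ndarray, grid_idx: np.ndarray, shape) -> MembershipMatrix:
    return MembershipMatrix(values=u, voxel_index=grid_idx, shape=tuple(shape))


def _drive(
    volume: ImageVolume,
    params: ClusterParams,
    init: InitSpec,
    step: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, float]],
    final_memberships: Callable[[np.ndarray], np.ndarray],
) -> ClusterState:
    """Alternate ``step`` (memberships + centroids + objective) to convergence.

    ``step(v) -> (u, v_new, objective)``; stops when ``max|v_new - v| <=
    epsilon``.  After the loop the memberships are recomputed from the final
    centroids so the returned state is an exact fixed point of the
    membership rule.
    """
    v = init_centroids(volume, params, init)
    obj_trace: list[float] = []
    cent_trace: list[tuple[float, ...]] = []
    delta_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        _, v_new, obj = step(v)
        delta = float(np.max(np.abs(v_new - v)))
        obj_trace.append(float(obj))
        cent_trace.append(tuple(float(t) for t in v_new))
        delta_trace.append(delta)
        v = v_new
        if delta <= params.epsilon:
            converged = True
            break
    u_final = final_memberships(v)
    mask_idx = np.flatnonzero(volume.mask_array().reshape(-1))
    state = ClusterState(
        centroids=v,
        memberships=_membership_matrix(u_final, mask_idx, volume.shape),
        iterations=it,
        converged=converged,
        objective_trace=tuple(obj_trace),
        centroid_trace=tuple(cent_trace),
        delta_trace=tuple(delta_trace),
    )
    state.memberships.validate(atol=1e-9)
    return state


def run_fcm(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> ClusterState:
    """Classic FCM.  The recorded objective is the within-cluster weighted
    square error ``J_m = sum_ik u_ik^m (x_k - v_i)^2``, non-increasing over
    iterations."""
    x = volume.masked_intensities()

    def step(v):
        u = fcm_memberships(x, v, params.m)
        v_new = fcm_centroids(x, u, params.m)
        d2 = (x[np.newaxis, :] - v_new[:, np.newaxis]) ** 2
        obj = float((u**params.m * d2).sum())
        return u, v_new, obj

    return _drive(volume, params, init, step, lambda v: fcm_memberships(x, v, params.m))


def run_kfcm(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> ClusterState:
    """Kernelized FCM.  Objective: ``sum_ik u_ik^m (1 - K(x_k, v_i))``."""
    x = volume.masked_intensities()
    kern = params.kernel

    def step(v):
        u = kfcm_memberships(x, v, params.m, kern)
        v_new = kfcm_centroids(x, v, u, params.m, kern)
        dk = 1.0 - kernel_value(x[np.newaxis, :], v_new[:, np.newaxis], kern)
        obj = float((u**params.m * dk).sum())
        return u, v_new, obj

    return _drive(volume, params, init, step, lambda v: kfcm_memberships(x, v, params.m, kern))


def run_sfcm(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> ClusterState:
    """Spatial FCM.

    Each outer iteration performs a single (non-iterated) FCM membership
    pass, computes the spatial function over the window, reweights the
    memberships by ``u^p h^q`` and updates the centroids from the spatial
    memberships.  Final labels come from the spatial memberships.
    """
    x = volume.masked_intensities()
    grid = _Grid(volume, params.neighborhood)

    def spatial_pass(v):
        u = fcm_memberships(x, v, params.m)
        h = spatial_function(u, grid)
        return spatial_memberships(u, h, params.p, params.q)

    def step(v):
        up = spatial_pass(v)
        v_new = fcm_centroids(x, up, params.m)
        d2 = (x[np.newaxis, :] - v_new[:, np.newaxis]) ** 2
        obj = float((up**params.m * d2).sum())
        return up, v_new, obj

    return _drive(volume, params, init, step, spatial_pass)


def run_skfcm(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> ClusterState:
    """Spatial kernelized FCM with neighborhood penalty term.

    The penalty window is the configured neighborhood with the center
    removed.  The kernel defaults to the Gaussian with the ``sigma^2``
    denominator convention.  Objective: penalized kernel distance sum.
    """
    x = volume.masked_intensities()
    kern = params.kernel
    if kern.family == "gaussian" and kern.variance_scale != "sigma2":
        kern = KernelSpec(family="gaussian", sigma=kern.sigma, variance_scale="sigma2")
    spec = params.neighborhood
    if spec.include_center:
        spec = NeighborhoodSpec(mode=spec.mode, size=spec.size, include_center=False)
    grid = _penalty_grid(volume, spec)

    def step(v):
        u = skfcm_memberships(x, v, params.m, kern, grid, params.alpha)
        v_new = skfcm_centroids(x, v, u, params.m, kern, grid, params.alpha)
        dk = 1.0 - kernel_value(x[np.newaxis, :], v_new[:, np.newaxis], kern)
        pen = np.stack([_skfcm_penalty(dk[i], grid, params.alpha) for i in range(len(v_new))])
        obj = float((u**params.m * (dk + pen)).sum())
        return u, v_new, obj

    return _drive(
        volume, params, init, step,
        lambda v: skfcm_memberships(x, v, params.m, kern, grid, params.alpha),
    )


def run_mskfcm(volume: ImageVolume, params: ClusterParams, init: InitSpec) -> ClusterState:
    """Modified spatial kernelized FCM: KFCM memberships, SFCM-style spatial
    reweighting, kernelized centroid update with the spatial memberships.

    Final labels come from the spatial memberships.
    """
    x = volume.masked_intensities()
    kern = params.kernel
    grid = _Grid(volume, params.neighborhood)

    def spatial_pass(v):
        u = kfcm_memberships(x, v, params.m, kern)
        h = spatial_function(u, grid)
        return spatial_memberships(u, h, params.p, params.q)

    def step(v):
        up = spatial_pass(v)
        v_new = kfcm_centroids(x, v, up, params.m, kern)
        dk = 1.0 - kernel_value(x[np.newaxis, :], v_new[:, np.newaxis], kern)
        obj = float((up**params.m * dk).sum())
        return up, v_new, obj

    return _drive(volume, params, init, step, spatial_pass)


ALGORITHMS: dict[str, Callable[[ImageVolume, ClusterParams, InitSpec], ClusterState]] = {
    "fcm": run_fcm,
    "kfcm": run_kfcm,
    "sfcm": run_sfcm,
    "skfcm": run_skfcm,
    "mskfcm": run_mskfcm,
}


def select_nodule_cluster(
    state: ClusterState, hint: Sequence[float] | None = None
) -> int:
    """Pick the cluster holding the candidate-nodule voxels.

    With a ``hint`` (sample intensities from the nodule) the cluster whose
    centroid is nearest the mean hint intensity is chosen.  Without one and
    with exactly three clusters, the middle cluster by centroid intensity
    is chosen — nodules sit at midrange HU between air-filled lung and
    dense tissue.
    """
    v = np.asarray(state.centroids, dtype=np.float64)
    if hint is not None and len(hint) > 0:
        target = float(np.mean(np.asarray(hint, dtype=np.float64)))
        return int(np.argmin(np.abs(v - target)))
    if len(v) == 3:
        return int(np.argsort(v, kind="stable")[1])
    raise ParameterError(
        f"cannot auto-select the nodule cluster with c={len(v)}; supply a hint"
    )
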