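"""Core domain types, kernel functions and neighborhood machinery.

The clustering solvers in :mod:`fuzzyroi.algorithms` operate on scalar CT
attenuation values (Hounsfield Units).  Everything here is pure computation:
image containers, kernel evaluations, window extraction and defuzzification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "ImageVolume",
    "NeighborhoodSpec",
    "KernelSpec",
    "ClusterParams",
    "MembershipMatrix",
    "ClusterState",
    "gaussian_kernel",
    "polynomial_kernel",
    "kernel_value",
    "extract_neighborhood",
    "defuzzify",
]

# 12-bit CT range in Hounsfield Units
HU_MIN = -1024.0
HU_MAX = 3071.0


class ParameterError(ValueError):
    """Invalid parameter value (non-positive sigma, even window size, ...)."""


@dataclass
class ImageVolume:
    """Scalar voxel grid with physical spacing and HU semantics.

    Parameters
    ----------
    voxels
        Intensity grid of shape ``(depth, rows, cols)``.  A single 2D slice
        is stored with ``depth == 1``; 2D input arrays are promoted.
    spacing
        Physical voxel size in mm per axis, ``(depth, row, col)`` order.
    lung_mask
        Optional boolean grid of the same shape marking voxels eligible for
        clustering.  Without it all voxels participate.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3:
            raise ParameterError(f"voxels must be 2D or 3D, got ndim={v.ndim}")
        if v.size == 0:
            raise ParameterError("empty volume")
        if not np.all(np.isfinite(v)):
            raise ParameterError("voxel intensities must be finite")
        self.voxels = v
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.lung_mask is not None:
            m = np.asarray(self.lung_mask)
            if m.ndim == 2:
                m = m[np.newaxis]
            if m.shape != v.shape:
                raise ParameterError(
                    f"lung_mask shape {m.shape} != voxel shape {v.shape}"
                )
            self.lung_mask = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    def mask_array(self) -> np.ndarray:
        """Boolean eligibility grid (all-true when no lung mask is set)."""
        if self.lung_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.lung_mask

    def masked_intensities(self) -> np.ndarray:
        """Flat vector of in-mask intensities, in C (flat-index) order."""
        return self.voxels[self.mask_array()]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Window used by the spatial algorithms.

    ``mode='2d'`` windows are squares confined to a single slice; ``'3d'``
    windows are rectangular prisms spanning ``size`` voxels along every
    axis (so a size-3 3D window covers the slice of the voxel plus the
    previous and following slice).  Windows are truncated at volume
    boundaries; no padding is ever applied.
    """

    mode: Literal["2d", "3d"] = "2d"
    size: int = 3
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ParameterError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ParameterError(f"window size must be a positive odd integer, got {self.size}")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2

    def footprint(self) -> np.ndarray:
        """Binary structuring element of shape (1|size, size, size)."""
        d = self.size if self.mode == "3d" else 1
        fp = np.ones((d, self.size, self.size), dtype=np.float64)
        if not self.include_center:
            fp[d // 2, self.half, self.half] = 0.0
        return fp

    def offsets(self) -> Iterator[tuple[int, int, int]]:
        h = self.half
        dz = range(-h, h + 1) if self.mode == "3d" else (0,)
        for z in dz:
            for r in range(-h, h + 1):
                for c in range(-h, h + 1):
                    if not self.include_center and z == 0 and r == 0 and c == 0:
                        continue
                    yield (z, r, c)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel used to emulate distances in a higher-dimensional feature space.

    Two families are supported: the Gaussian radial basis function
    ``K(x, y) = exp(-(x - y)^2 / D)`` where the denominator ``D`` is either
    ``2 sigma^2`` or ``sigma^2`` depending on ``variance_scale`` (both
    conventions appear in the literature; they coincide under
    ``sigma' = sigma * sqrt(2)``), and the polynomial kernel
    ``K(x, y) = (x y + b)^d``.
    """

    family: Literal["gaussian", "polynomial"] = "gaussian"
    sigma: float = 300.0  # HU; sensible for thoracic CT contrast
    variance_scale: Literal["2sigma2", "sigma2"] = "2sigma2"
    b: float = 0.0
    d: int = 2

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "polynomial"):
            raise ParameterError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian" and not self.sigma > 0:
            raise ParameterError(f"gaussian sigma must be positive, got {self.sigma}")
        if self.variance_scale not in ("2sigma2", "sigma2"):
            raise ParameterError(f"variance_scale must be '2sigma2' or 'sigma2'")
        if self.family == "polynomial" and (self.d < 0 or int(self.d) != self.d):
            raise ParameterError(f"polynomial degree must be a non-negative integer, got {self.d}")

    @property
    def denominator(self) -> float:
        return 2.0 * self.sigma**2 if self.variance_scale == "2sigma2" else self.sigma**2


def gaussian_kernel(x, y, spec: KernelSpec):
    """Gaussian RBF similarity in (0, 1]; 1 iff x == y.  Vectorized."""
    if spec.family != "gaussian":
        raise ParameterError("gaussian_kernel requires a gaussian KernelSpec")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return np.exp(-((x - y) ** 2) / spec.denominator)


def polynomial_kernel(x, y, spec: KernelSpec):
    """Polynomial kernel (x*y + b)^d.  Vectorized."""
    if spec.family != "polynomial":
        raise ParameterError("polynomial_kernel requires a polynomial KernelSpec")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return (x * y + spec.b) ** int(spec.d)


def kernel_value(x, y, spec: KernelSpec):
    """Dispatch on the kernel family."""
    if spec.family == "gaussian":
        return gaussian_kernel(x, y, spec)
    return polynomial_kernel(x, y, spec)


@dataclass(frozen=True)
class ClusterParams:
    """Parameters shared by all solvers.

    Defaults follow the ranges that perform best for thoracic CT ROI
    detection: three clusters, a 3x3 spatial window, sigma in the low
    hundreds of HU, p and q around 1 and alpha in (0.1, 0.2).
    """

    c: int = 3
    m: float = 2.0
    epsilon: float = 1e-3  # max-norm centroid change, HU
    max_iter: int = 200
    p: float = 1.0
    q: float = 1.0
    alpha: float = 0.15
    kernel: KernelSpec = field(default_factory=KernelSpec)
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ParameterError(f"need at least one cluster, got c={self.c}")
        if not self.m > 1:
            raise ParameterError(f"fuzzifier m must be > 1, got {self.m}")
        if not self.epsilon > 0:
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")
        if self.max_iter < 1:
            raise ParameterError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.p < 0 or self.q < 0:
            raise ParameterError(f"spatial exponents p, q must be >= 0, got p={self.p} q={self.q}")
        if not (0 < self.alpha < 1):
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")

    def with_(self, **kw) -> "ClusterParams":
        return replace(self, **kw)


@dataclass
class MembershipMatrix:
    """c x n fuzzy memberships with a mapping from column to voxel.

    ``values[i, k]`` is the degree in [0, 1] to which voxel ``k`` belongs to
    cluster ``i``; each column sums to 1.  ``voxel_index`` holds the flat
    (C-order) index of each column's voxel within ``shape``.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.ndim != 2:
            raise ParameterError("membership values must be a c x n matrix")
        if self.voxel_index.shape != (self.values.shape[1],):
            raise ParameterError("voxel_index length must equal the number of columns")

    @property
    def n_clusters(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.values < -atol) or np.any(self.values > 1 + atol):
            raise ParameterError("memberships outside [0, 1]")
        col = self.values.sum(axis=0)
        if not np.allclose(col, 1.0, atol=atol, rtol=0):
            raise ParameterError("membership columns must sum to 1")

    def to_grids(self) -> np.ndarray:
        """Dense (c, depth, rows, cols) membership grids, 0 outside the mask."""
        out = np.zeros((self.n_clusters,) + tuple(self.shape), dtype=np.float64)
        flat = out.reshape(self.n_clusters, -1)
        flat[:, self.voxel_index] = self.values
        return out


@dataclass
class ClusterState:
    """Result of one solver run: centroids, memberships and bookkeeping."""

    centroids: np.ndarray
    memberships: MembershipMatrix
    iterations: int
    converged: bool
    objective_trace: tuple[float, ...] = ()
    centroid_trace: tuple[tuple[float, ...], ...] = ()
    delta_trace: tuple[float, ...] = ()

    def labels(self) -> np.ndarray:
        """Crisp label grid (see :func:`defuzzify`)."""
        return defuzzify(self.memberships)


def extract_neighborhood(
    volume: ImageVolume,
    voxel: Sequence[int],
    spec: NeighborhoodSpec,
) -> list[tuple[int, int, int]]:
    """Coordinates of the window around ``voxel``, truncated at boundaries.

    In 2D mode the window never crosses slice boundaries.  The center is
    excluded iff ``spec.include_center`` is false.
    """
    z0, r0, c0 = (int(v) for v in voxel)
    D, R, C = volume.shape
    if not (0 <= z0 < D and 0 <= r0 < R and 0 <= c0 < C):
        raise ParameterError(f"voxel {voxel} outside volume of shape {volume.shape}")
    out = []
    for dz, dr, dc in spec.offsets():
        z, r, c = z0 + dz, r0 + dr, c0 + dc
        if 0 <= z < D and 0 <= r < R and 0 <= c < C:
            out.append((z, r, c))
    return out


def defuzzify(memberships: MembershipMatrix) -> np.ndarray:
    """Assign each voxel its maximal-membership cluster.

    Ties break to the lowest cluster index.  Voxels outside the clustered
    set (masked out) get label -1.
    """
    labels = np.full(memberships.shape, -1, dtype=np.int32)
    labels.reshape(-1)[memberships.voxel_index] = np.argmax(memberships.values, axis=0)
    return labels
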