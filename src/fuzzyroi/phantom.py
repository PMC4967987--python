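"""Synthetic CT-like phantoms with ground-truth nodule masks.

The generator emulates the pieces of a thoracic CT slice that matter to
intensity-based clustering: an elliptical lung region of low-attenuation
parenchyma (~ -850 HU) inside a soft-tissue chest wall (~ 40 HU), bright
vessel tubes, spherical nodules at midrange HU (~ -50), and additive
Gaussian noise.  Intensities are clipped to the 12-bit HU range
[-1024, 3071].  All randomness is seeded, so the same spec always yields
the same volume voxel-for-voxel.

What it does not emulate: anatomical lung texture, partial-volume effects,
juxtapleural attachment, scanner reconstruction artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import HU_MAX, HU_MIN, ImageVolume, ParameterError
from .evaluation import NoduleMask

__all__ = ["Nodule", "Vessel", "PhantomSpec", "generate_phantom", "generate_consensus"]


@dataclass(frozen=True)
class Nodule:
    """Sphere of given voxel radius and mean HU."""

    center: tuple[int, int, int]
    radius: float = 4.0
    hu: float = -50.0


@dataclass(frozen=True)
class Vessel:
    """Axis-aligned tube from ``start`` to ``end`` of given radius and HU."""

    start: tuple[int, int, int]
    end: tuple[int, int, int]
    radius: float = 1.5
    hu: float = 30.0


def _default_nodules() -> tuple[Nodule, ...]:
    return (Nodule(center=(1, 22, 40), radius=4.0, hu=-50.0),)


def _default_vessels() -> tuple[Vessel, ...]:
    return (
        Vessel(start=(1, 40, 14), end=(1, 40, 50), radius=1.5, hu=30.0),
        Vessel(start=(1, 14, 26), end=(1, 48, 26), radius=1.5, hu=30.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic CT volume.

    Defaults give the standard test phantom: 3 slices of 64 x 64, one
    radius-4 nodule, two vessel segments, noise sd 20 HU.  The HU means
    place the nodule midway between air-filled lung and soft tissue, the
    regime in which fuzzy ROI detection operates.
    """

    shape: tuple[int, int, int] = (3, 64, 64)
    background_hu: float = -850.0
    tissue_hu: float = 40.0
    nodules: tuple[Nodule, ...] = field(default_factory=_default_nodules)
    vessels: tuple[Vessel, ...] = field(default_factory=_default_vessels)
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = (2.0, 0.7, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ParameterError(f"shape must be (depth, rows, cols) >= 1, got {self.shape}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for nod in self.nodules:
            if nod.radius < 1:
                raise ParameterError("nodule radius must be >= 1 voxel")
        for ves in self.vessels:
            if ves.radius < 1:
                raise ParameterError("vessel radius must be >= 1 voxel")
            diffs = [a != b for a, b in zip(ves.start, ves.end)]
            if sum(diffs) > 1:
                raise ParameterError(f"vessel {ves} is not axis-aligned")


def _lung_region(shape: tuple[int, int, int]) -> np.ndarray:
    """Elliptical in-plane lung region spanning all slices."""
    _, R, C = shape
    rr, cc = np.mgrid[0:R, 0:C]
    a, b = 0.42 * R, 0.45 * C
    ell = ((rr - (R - 1) / 2) / a) ** 2 + ((cc - (C - 1) / 2) / b) ** 2 <= 1.0
    return np.broadcast_to(ell, shape).copy()


def _sphere(shape, center, radius) -> np.ndarray:
    zz, rr, cc = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    d2 = (zz - center[0]) ** 2 + (rr - center[1]) ** 2 + (cc - center[2]) ** 2
    return d2 <= radius**2


def _tube(shape, ves: Vessel) -> np.ndarray:
    lo = np.minimum(ves.start, ves.end)
    hi = np.maximum(ves.start, ves.end)
    zz, rr, cc = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    axes = [zz, rr, cc]
    along = int(np.argmax(hi - lo)) if np.any(hi > lo) else 0
    within = (axes[along] >= lo[along]) & (axes[along] <= hi[along])
    d2 = sum(
        (axes[ax] - lo[ax]) ** 2 for ax in range(3) if ax != along
    )
    return within & (d2 <= ves.radius**2)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, NoduleMask, np.ndarray]:
    """Render a phantom: (volume with lung mask attached, truth mask, lung mask).

    Structures must lie inside the elliptical lung region; the truth mask
    is the union of the nodule spheres and is always a subset of the lung
    mask.
    """
    shape = spec.shape
    lung = _lung_region(shape)
    img = np.full(shape, spec.tissue_hu, dtype=np.float64)
    img[lung] = spec.background_hu
    for ves in spec.vessels:
        t = _tube(shape, ves)
        if np.any(t & ~lung):
            raise ParameterError(f"vessel {ves} extends outside the lung region")
        img[t] = ves.hu
    truth = np.zeros(shape, dtype=bool)
    for nod in spec.nodules:
        s = _sphere(shape, nod.center, nod.radius)
        if not np.any(s):
            raise ParameterError(f"nodule {nod} covers no voxels")
        if np.any(s & ~lung):
            raise ParameterError(f"nodule {nod} extends outside the lung region")
        img[s] = nod.hu
        truth |= s
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, HU_MIN, HU_MAX)
    vol = ImageVolume(voxels=img, spacing=spec.spacing, lung_mask=lung)
    return vol, NoduleMask(grid=truth, semantics="binary"), lung


def generate_consensus(
    truth: NoduleMask, levels: Sequence[float] = (1000.0, 750.0, 500.0, 250.0)
) -> NoduleMask:
    """Grade a binary truth mask into consensus scores by erosion depth.

    For each connected nodule, the core voxels surviving the deepest
    erosion score ``levels[0]`` (1000 by default) and successive outward
    shells take the following levels; shells beyond the list take the last
    level.  A single-voxel nodule is its own core and scores 1000.
    Thresholding the result at a score above ``levels[1]`` recovers exactly
    each nodule's eroded core.
    """
    if truth.semantics != "binary":
        raise ParameterError("generate_consensus expects a binary truth mask")
    g = truth.grid
    scores = np.zeros(g.shape, dtype=np.float64)
    labeled, n_comp = ndimage.label(g)
    for comp in range(1, n_comp + 1):
        m = labeled == comp
        # erosion depth survived by each voxel of this component
        depth = np.zeros(g.shape, dtype=np.int64)
        cur = m.copy()
        while np.any(cur):
            depth += cur
            cur = ndimage.binary_erosion(cur)
        dmax = int(depth[m].max())
        shell = dmax - depth[m]  # 0 at the core, growing outward
        idx = np.minimum(shell, len(levels) - 1)
        scores[m] = np.asarray(levels, dtype=np.float64)[idx]
    return NoduleMask(grid=scores, semantics="consensus")
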