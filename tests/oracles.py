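"""Independent naive scalar-loop implementations of every update rule.

These deliberately mirror the update formulas one voxel and one cluster at
a time, with explicit Python loops and no shared code with the package's
vectorized implementations.  They are the reference the fast paths are
checked against on tiny images.
"""

from __future__ import annotations

import math


def kernel(x, y, family="gaussian", sigma=1.0, variance_scale="2sigma2", b=0.0, d=2):
    if family == "gaussian":
        den = 2.0 * sigma * sigma if variance_scale == "2sigma2" else sigma * sigma
        return math.exp(-((x - y) ** 2) / den)
    return (x * y + b) ** d


def fcm_memberships(xs, vs, m):
    """u[i][k] per the ratio-of-distances membership rule."""
    c, n = len(vs), len(xs)
    u = [[0.0] * n for _ in range(c)]
    for k in range(n):
        zero = [i for i in range(c) if xs[k] == vs[i]]
        if zero:
            for i in zero:
                u[i][k] = 1.0 / len(zero)
            continue
        for i in range(c):
            s = 0.0
            for j in range(c):
                s += (abs(xs[k] - vs[i]) / abs(xs[k] - vs[j])) ** (2.0 / (m - 1.0))
            u[i][k] = 1.0 / s
    return u


def fcm_centroids(xs, u, m):
    c = len(u)
    vs = []
    for i in range(c):
        num = sum((u[i][k] ** m) * xs[k] for k in range(len(xs)))
        den = sum(u[i][k] ** m for k in range(len(xs)))
        vs.append(num / den)
    return vs


def kfcm_memberships(xs, vs, m, **kw):
    c, n = len(vs), len(xs)
    u = [[0.0] * n for _ in range(c)]
    for k in range(n):
        dk = [1.0 - kernel(xs[k], vs[i], **kw) for i in range(c)]
        zero = [i for i in range(c) if dk[i] <= 0.0]
        if zero:
            for i in zero:
                u[i][k] = 1.0 / len(zero)
            continue
        den = sum(dk[j] ** (-1.0 / (m - 1.0)) for j in range(c))
        for i in range(c):
            u[i][k] = dk[i] ** (-1.0 / (m - 1.0)) / den
    return u


def kfcm_centroids(xs, vs_prev, u, m, **kw):
    c = len(u)
    out = []
    for i in range(c):
        num = den = 0.0
        for k in range(len(xs)):
            w = (u[i][k] ** m) * kernel(xs[k], vs_prev[i], **kw)
            num += w * xs[k]
            den += w
        out.append(num / den)
    return out


def neighbors(shape, voxel, size, mode="2d", include_center=True):
    """Window coordinates around voxel, truncated at boundaries."""
    D, R, C = shape
    z0, r0, c0 = voxel
    h = (size - 1) // 2
    zs = range(z0 - h, z0 + h + 1) if mode == "3d" else [z0]
    out = []
    for z in zs:
        for r in range(r0 - h, r0 + h + 1):
            for c in range(c0 - h, c0 + h + 1):
                if not (0 <= z < D and 0 <= r < R and 0 <= c < C):
                    continue
                if not include_center and (z, r, c) == (z0, r0, c0):
                    continue
                out.append((z, r, c))
    return out


def spatial_function(u_grid, size, mode="2d", include_center=True, mask=None):
    """h[i] grids: per-voxel window sums of cluster-i memberships.

    ``u_grid[i][z][r][c]`` holds memberships; ``mask`` (same shape) limits
    which voxels exist.
    """
    c = len(u_grid)
    D = len(u_grid[0])
    R = len(u_grid[0][0])
    C = len(u_grid[0][0][0])
    h = [[[[0.0] * C for _ in range(R)] for _ in range(D)] for _ in range(c)]
    for i in range(c):
        for z in range(D):
            for r in range(R):
                for cc in range(C):
                    if mask is not None and not mask[z][r][cc]:
                        continue
                    s = 0.0
                    for (nz, nr, nc) in neighbors((D, R, C), (z, r, cc), size, mode, include_center):
                        if mask is None or mask[nz][nr][nc]:
                            s += u_grid[i][nz][nr][nc]
                    h[i][z][r][cc] = s
    return h


def spatial_memberships(u, h, p, q):
    """u'[i][k] = u^p h^q normalized over clusters; fallback on zero sum."""
    c, n = len(u), len(u[0])
    out = [[0.0] * n for _ in range(c)]
    for k in range(n):
        nums = [(u[i][k] ** p) * (h[i][k] ** q) for i in range(c)]
        den = sum(nums)
        if den <= 0:
            nums = [u[i][k] for i in range(c)]
            den = sum(nums)
        for i in range(c):
            out[i][k] = nums[i] / den
    return out


def skfcm_memberships(xs, vs, m, alpha, nbr_lists, **kw):
    """Penalized kernelized memberships.

    ``nbr_lists[k]`` lists the flat indices of voxel k's (center-free)
    window members.
    """
    c, n = len(vs), len(xs)
    u = [[0.0] * n for _ in range(c)]
    for k in range(n):
        brackets = []
        for i in range(c):
            dk = 1.0 - kernel(xs[k], vs[i], **kw)
            nbrs = nbr_lists[k]
            pen = 0.0
            if nbrs:
                pen = alpha / len(nbrs) * sum(1.0 - kernel(xs[r], vs[i], **kw) for r in nbrs)
            brackets.append(dk + pen)
        zero = [i for i in range(c) if brackets[i] <= 0.0]
        if zero:
            for i in zero:
                u[i][k] = 1.0 / len(zero)
            continue
        den = sum(br ** (-1.0 / (m - 1.0)) for br in brackets)
        for i in range(c):
            u[i][k] = brackets[i] ** (-1.0 / (m - 1.0)) / den
    return u


def skfcm_centroids(xs, vs_prev, u, m, alpha, nbr_lists, **kw):
    c = len(u)
    out = []
    for i in range(c):
        num = den = 0.0
        for k in range(len(xs)):
            Kk = kernel(xs[k], vs_prev[i], **kw)
            nbrs = nbr_lists[k]
            pen_x = pen_1 = 0.0
            if nbrs:
                pen_x = alpha / len(nbrs) * sum(
                    kernel(xs[r], vs_prev[i], **kw) * xs[r] for r in nbrs
                )
                pen_1 = alpha / len(nbrs) * sum(kernel(xs[r], vs_prev[i], **kw) for r in nbrs)
            w = u[i][k] ** m
            num += w * (Kk * xs[k] + pen_x)
            den += w * (Kk + pen_1)
        out.append(num / den)
    return out


def defuzzify(u):
    """Per-voxel argmax with lowest-index tie break."""
    c, n = len(u), len(u[0])
    labels = []
    for k in range(n):
        best, arg = -1.0, 0
        for i in range(c):
            if u[i][k] > best:
                best, arg = u[i][k], i
        labels.append(arg)
    return labels
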