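"""Independent brute-force oracles used to cross-check the package.

Everything here is written the slow, obvious way (python loops, full
pairwise enumeration) and deliberately shares no code with
``uterseg``.
"""

from __future__ import annotations

import math

import numpy as np


def reference_fcm(x, c, m, tol=1e-10, max_iter=2000, init_centers=None):
    """Naive scalar FCM: literal alternating update loops.

    Returns (centers, memberships) with memberships of shape (n, c).
    """
    x = [float(v) for v in x]
    n = len(x)
    if init_centers is None:
        xs = sorted(x)
        centers = [xs[min(n - 1, int((2 * i + 1) / (2 * c) * n))] for i in range(c)]
    else:
        centers = [float(v) for v in init_centers]
    U = [[0.0] * c for _ in range(n)]
    for _ in range(max_iter):
        for k in range(n):
            d = [abs(x[k] - centers[i]) for i in range(c)]
            if min(d) == 0.0:
                for i in range(c):
                    U[k][i] = 0.0
                U[k][d.index(0.0)] = 1.0
            else:
                for i in range(c):
                    s = sum((d[i] / d[j]) ** (2.0 / (m - 1.0)) for j in range(c))
                    U[k][i] = 1.0 / s
        new_centers = []
        for i in range(c):
            num = sum(U[k][i] ** m * x[k] for k in range(n))
            den = sum(U[k][i] ** m for k in range(n))
            new_centers.append(num / den)
        shift = max(abs(a - b) for a, b in zip(new_centers, centers))
        centers = new_centers
        if shift < tol:
            break
    return np.asarray(centers), np.asarray(U)


def reference_overlap(M, A):
    """Voxel-by-voxel set counting with python loops."""
    n_m = n_a = n_tp = n_fp = 0
    for mm, aa in zip(M.ravel(), A.ravel()):
        if mm:
            n_m += 1
        if aa:
            n_a += 1
        if mm and aa:
            n_tp += 1
        if aa and not mm:
            n_fp += 1
    return n_m, n_a, n_tp, n_fp


def reference_surface_points(mask, spacing):
    """Foreground voxels with a background 6-neighbour (outside = bg)."""
    nx, ny, nz = mask.shape
    pts = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                boundary = False
                for di, dj, dk in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
                ):
                    a, b, cc = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= cc < nz):
                        boundary = True
                        break
                    if not mask[a, b, cc]:
                        boundary = True
                        break
                if boundary:
                    pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    return pts


def reference_surface_distances(M, A, spacing):
    """Exhaustive min/max over all surface point pairs (O(n^2))."""
    pm = reference_surface_points(M, spacing)
    pa = reference_surface_points(A, spacing)

    def directed(src, dst):
        mins = []
        for p in src:
            best = math.inf
            for q in dst:
                d = math.dist(p, q)
                if d < best:
                    best = d
            mins.append(best)
        return mins

    d_ma = directed(pm, pa)
    d_am = directed(pa, pm)
    hd = max(max(d_ma), max(d_am))
    md = (sum(d_ma) / len(d_ma) + sum(d_am) / len(d_am)) / 2.0
    return hd, md


def reference_valley_threshold(values, bins, smooth_width):
    """Brute-force valley search: histogram, centred moving average,
    scan for local maxima (edges count), take the minimum bin between
    the last two maxima."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    w = smooth_width + (1 - smooth_width % 2)
    half = w // 2
    sm = []
    ext = [0.0] * half + list(counts.astype(float)) + [0.0] * half
    for i in range(len(counts)):
        sm.append(sum(ext[i : i + w]) / w)
    # local maxima with edges treated as falling off to -1
    padded = [-1.0] + sm + [-1.0]
    maxima = []
    i = 1
    while i < len(padded) - 1:
        if padded[i] > padded[i - 1]:
            j = i
            while j + 1 < len(padded) - 1 and padded[j + 1] == padded[j]:
                j += 1
            if padded[j + 1] < padded[j]:
                maxima.append(i - 1)  # left edge of any plateau
            i = j + 1
        else:
            i += 1
    if len(maxima) < 2:
        return None, maxima
    a, b = maxima[-2], maxima[-1]
    valley = min(range(a, b + 1), key=lambda i: sm[i])
    thr = (edges[valley] + edges[valley + 1]) / 2.0
    return thr, maxima
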