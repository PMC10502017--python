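"""Skeleton-path analysis shared by the classical detection and pose backends.

A binary particle mask is skeletonized and its longest geodesic path
extracted (double breadth-first search, which also discards small
spurs).  The path is then segmented into k maximally-straight runs by
exact changepoint search minimizing the summed total-least-squares line
residual: k=2 recovers the two arms of a hinge (the changepoint is the
vertex region), k=3 recovers arm-base-arm of a two-vertex device.
Residuals per run are computed in O(1) from prefix sums, so the search
is exact, deterministic and fast.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "skeleton_path",
    "PathSplit",
    "split_path",
    "fit_line",
    "intersect_lines",
    "segment_coverage",
]

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the skeleton of ``mask``.

    Returns an ordered (n, 2) array of (x, y) pixel coordinates, empty
    when the mask has no skeleton.  Spurs off the main path are dropped.
    """
    skel = skeletonize(mask.astype(bool))
    ys, xs = np.nonzero(skel)
    if len(xs) == 0:
        return np.empty((0, 2))
    pixels = {(int(y), int(x)) for y, x in zip(ys, xs)}

    def bfs(start):
        seen = {start: None}
        queue = deque([start])
        last = start
        while queue:
            cur = queue.popleft()
            last = cur
            for dy, dx in _NEIGH8:
                nxt = (cur[0] + dy, cur[1] + dx)
                if nxt in pixels and nxt not in seen:
                    seen[nxt] = cur
                    queue.append(nxt)
        return last, seen

    start = (int(ys[0]), int(xs[0]))
    far, _ = bfs(start)
    end, parents = bfs(far)
    path = []
    cur = end
    while cur is not None:
        path.append(cur)
        cur = parents[cur]
    arr = np.array(path, dtype=float)
    return arr[:, ::-1]  # (y, x) -> (x, y)


class _PrefixFitter:
    """O(1) total-least-squares residuals on contiguous path intervals."""

    def __init__(self, pts: np.ndarray) -> None:
        x, y = pts[:, 0], pts[:, 1]
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])

    def sse(self, i, j):
        """Summed squared perpendicular residual of the best line through
        path[i:j]; vectorized over integer arrays i, j (j - i >= 2)."""
        i = np.asarray(i)
        j = np.asarray(j)
        n = (j - i).astype(float)
        mx = (self.sx[j] - self.sx[i]) / n
        my = (self.sy[j] - self.sy[i]) / n
        cxx = (self.sxx[j] - self.sxx[i]) / n - mx * mx
        cyy = (self.syy[j] - self.syy[i]) / n - my * my
        cxy = (self.sxy[j] - self.sxy[i]) / n - mx * my
        half_tr = (cxx + cyy) / 2.0
        det = cxx * cyy - cxy * cxy
        lam_min = half_tr - np.sqrt(np.maximum(half_tr * half_tr - det, 0.0))
        return n * np.maximum(lam_min, 0.0)


@dataclass
class PathSplit:
    """Result of segmenting an ordered path into straight runs."""

    breaks: tuple[int, ...]  # changepoint indices into the path
    runs: list[np.ndarray]  # pixel runs, in path order
    lines: list[tuple[np.ndarray, np.ndarray]]  # (mean, unit direction) per run
    rms: list[float]  # perpendicular RMS residual per run
    total_sse: float


def _run_stats(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mean, direction, rms = fit_line(pts)
    return mean, direction, rms


def split_path(path: np.ndarray, k: int, min_len: int = 8) -> PathSplit | None:
    """Exact best split of an ordered path into ``k`` straight runs.

    Minimizes the summed TLS residual over all changepoint placements
    with every run at least ``min_len`` pixels.  Supports k in {1, 2, 3}.
    Returns None when the path is too short.
    """
    n = len(path)
    if n < k * min_len:
        return None
    fitter = _PrefixFitter(path)
    if k == 1:
        breaks: tuple[int, ...] = ()
    elif k == 2:
        cand = np.arange(min_len, n - min_len + 1)
        if len(cand) == 0:
            return None
        total = fitter.sse(np.zeros_like(cand), cand) + fitter.sse(cand, np.full_like(cand, n))
        breaks = (int(cand[np.argmin(total)]),)
    elif k == 3:
        ii, jj = np.meshgrid(
            np.arange(min_len, n - 2 * min_len + 1),
            np.arange(2 * min_len, n - min_len + 1),
            indexing="ij",
        )
        valid = jj - ii >= min_len
        if not valid.any():
            return None
        i_flat, j_flat = ii[valid], jj[valid]
        total = (
            fitter.sse(np.zeros_like(i_flat), i_flat)
            + fitter.sse(i_flat, j_flat)
            + fitter.sse(j_flat, np.full_like(j_flat, n))
        )
        best = int(np.argmin(total))
        breaks = (int(i_flat[best]), int(j_flat[best]))
    else:
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    bounds = (0, *breaks, n)
    runs = [path[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    lines, rms = [], []
    for run in runs:
        mean, direction, r = _run_stats(run)
        lines.append((mean, direction))
        rms.append(r)
    total_sse = float(sum(len(run) * r * r for run, r in zip(runs, rms)))
    return PathSplit(breaks=breaks, runs=runs, lines=lines, rms=rms, total_sse=total_sse)


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line fit.

    Returns (mean point, unit direction, RMS perpendicular residual).
    """
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    if len(pts) < 2:
        return mean, np.array([1.0, 0.0]), 0.0
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    residuals = centered @ np.array([-direction[1], direction[0]])
    return mean, direction, float(np.sqrt(np.mean(residuals**2)))


def intersect_lines(
    m1: np.ndarray, d1: np.ndarray, m2: np.ndarray, d2: np.ndarray
) -> np.ndarray | None:
    """Intersection of two parametric lines; None when near-parallel."""
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < 1e-6:
        return None
    delta = m2 - m1
    t = (delta[0] * d2[1] - delta[1] * d2[0]) / cross
    return m1 + t * d1


def segment_coverage(
    points: np.ndarray, segments: list[tuple[np.ndarray, np.ndarray]], halfwidth: float
) -> float:
    """Fraction of ``points`` within ``halfwidth`` of any line segment.

    Each segment is an (endpoint_a, endpoint_b) pair.  Used as the
    two-arm shape score of the classical detector.
    """
    if len(points) == 0:
        return 0.0
    pts = np.asarray(points, dtype=float)
    best = np.full(len(pts), np.inf)
    for a, b in segments:
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dist = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            dist = np.linalg.norm(pts - proj, axis=1)
        best = np.minimum(best, dist)
    return float(np.mean(best <= halfwidth))
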