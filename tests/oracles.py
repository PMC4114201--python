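"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops, deliberately independent of the
package's vectorised implementations, so that agreement is evidence of
correctness rather than shared code.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def point_in_polygon(px: float, py: float, verts: np.ndarray) -> bool:
    """Even-odd (ray casting) point-in-polygon test, one point at a time."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            if px < x_cross:
                inside = not inside
    return inside


def rasterize_bruteforce(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-centre rasterisation by exhaustive per-pixel testing."""
    rows, cols = shape
    grid = np.zeros((rows, cols), dtype=bool)
    for y in range(rows):
        for x in range(cols):
            grid[y, x] = point_in_polygon(x + 0.5, y + 0.5, verts)
    return grid


def initial_box_bruteforce(
    roi_grid: np.ndarray, init_area_scale: float = 1.25
) -> tuple[int, int, int, int]:
    """Initial spillover box (left, right, top, bottom) from first principles:
    centroid-centred, ROI-bounding-box aspect, area = scale * ROI area,
    rounded outward, clipped to the image."""
    rows, cols = roi_grid.shape
    ys, xs, n = [], [], 0
    for y in range(rows):
        for x in range(cols):
            if roi_grid[y, x]:
                ys.append(y)
                xs.append(x)
                n += 1
    cy = sum(ys) / n + 0.5
    cx = sum(xs) / n + 0.5
    bw = max(xs) - min(xs) + 1
    bh = max(ys) - min(ys) + 1
    area = init_area_scale * n
    w = math.sqrt(area * bw / bh)
    h = math.sqrt(area * bh / bw)
    left = max(int(math.floor(cx - w / 2)), 0)
    right = min(int(math.ceil(cx + w / 2)), cols)
    top = max(int(math.floor(cy - h / 2)), 0)
    bottom = min(int(math.ceil(cy + h / 2)), rows)
    return left, right, top, bottom


def spillover_bruteforce(
    channel: np.ndarray,
    roi_grid: np.ndarray,
    threshold: float,
    init_area_scale: float = 1.25,
    side_fraction: float = 0.10,
) -> tuple[tuple[int, int, int, int], int]:
    """Loop-level simulation of the expanding-box side rule.

    Each iteration: for each 1-pixel-wide side strip of the current box
    (corners belong to both adjacent sides), count suprathreshold pixels; any
    side with a fraction >= side_fraction moves outward one pixel unless it
    is at the image border.  Returns the final box and the suprathreshold
    count outside the ROI, inside the box.
    """
    rows, cols = channel.shape
    left, right, top, bottom = initial_box_bruteforce(roi_grid, init_area_scale)

    while True:
        counts = {"left": 0, "right": 0, "top": 0, "bottom": 0}
        for y in range(top, bottom):
            if channel[y, left] > threshold:
                counts["left"] += 1
            if channel[y, right - 1] > threshold:
                counts["right"] += 1
        for x in range(left, right):
            if channel[top, x] > threshold:
                counts["top"] += 1
            if channel[bottom - 1, x] > threshold:
                counts["bottom"] += 1
        height = bottom - top
        width = right - left
        moved = False
        if counts["left"] / height >= side_fraction and left > 0:
            left -= 1
            moved = True
        if counts["right"] / height >= side_fraction and right < cols:
            right += 1
            moved = True
        if counts["top"] / width >= side_fraction and top > 0:
            top -= 1
            moved = True
        if counts["bottom"] / width >= side_fraction and bottom < rows:
            bottom += 1
            moved = True
        if not moved:
            break

    spill = 0
    for y in range(top, bottom):
        for x in range(left, right):
            if channel[y, x] > threshold and not roi_grid[y, x]:
                spill += 1
    return (left, right, top, bottom), spill


def mannwhitney_exact_enumeration(g1, g2) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings.

    Valid for tie-free data.  Returns (U1, p).  The two-sided p doubles the
    smaller tail of the exact permutation distribution of U (capped at 1).
    """
    g1 = list(g1)
    g2 = list(g2)
    n1, n2 = len(g1), len(g2)
    pooled = g1 + g2
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"

    def u_stat(first_idx):
        first = [pooled[i] for i in first_idx]
        second = [pooled[i] for i in range(n1 + n2) if i not in first_idx]
        return sum(1 for a in first for b in second if a > b)

    u_obs = sum(1 for a in g1 for b in g2 if a > b)
    us = [u_stat(set(idx)) for idx in combinations(range(n1 + n2), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))


def random_star_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    n_vertices: int = 12,
    wobble: float = 0.4,
) -> np.ndarray:
    """A random simple (star-shaped) polygon for fixture generation."""
    spacing = 2 * math.pi / n_vertices
    theta = np.arange(n_vertices) * spacing + rng.uniform(0, 0.9 * spacing, n_vertices)
    radii = radius * rng.uniform(1 - wobble, 1 + wobble, n_vertices)
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(theta), cy + radii * np.sin(theta)])
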