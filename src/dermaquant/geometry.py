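"""Angle and ellipse primitives used by the generator and the measurement code.

Coordinate convention (used everywhere in this package): 0-based pixel
indices, origin at the top-left corner, x = column index increasing
rightward, y = row index increasing downward.  Angles of undirected lines
are measured in degrees from the +x axis toward +y and live in [0, 180).
"""

from __future__ import annotations

import numpy as np


def fold_acute(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Fold an angle difference to the acute range [0, 90].

    Undirected lines at ``a`` and ``a + 180`` are the same line, so the
    angle between two lines is first reduced modulo 180 and then reflected
    about 90 degrees.
    """
    m = np.mod(angle_deg, 180.0)
    return np.where(m > 90.0, 180.0 - m, m) if isinstance(m, np.ndarray) else (180.0 - m if m > 90.0 else m)


def acute_angle_between(a_deg, b_deg):
    """Acute angle in [0, 90] between two undirected lines."""
    return fold_acute(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def ellipse_pixels(
    center_y: float,
    center_x: float,
    semi_major: float,
    semi_minor: float,
    angle_deg: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) covered by a rotated filled ellipse.

    ``angle_deg`` orients the major axis from the +x axis toward +y.
    Pixels outside ``shape`` are clipped away.
    """
    h, w = shape
    r = float(max(semi_major, semi_minor)) + 1.0
    r0 = max(int(np.floor(center_y - r)), 0)
    r1 = min(int(np.ceil(center_y + r)) + 1, h)
    c0 = max(int(np.floor(center_x - r)), 0)
    c1 = min(int(np.ceil(center_x + r)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    dy = rows[:, None] - center_y
    dx = cols[None, :] - center_x
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    u = (dx * ct + dy * st) / semi_major
    v = (-dx * st + dy * ct) / semi_minor
    inside = u * u + v * v <= 1.0
    rr, cc = np.nonzero(inside)
    return rr + r0, cc + c0


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching (start, end) intervals."""
    if not intervals:
        return []
    srt = sorted((float(a), float(b)) for a, b in intervals)
    merged = [list(srt[0])]
    for a, b in srt[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]
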