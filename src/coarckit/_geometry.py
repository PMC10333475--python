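"""Planar piecewise-curve primitives used by the arch generator and morphometry.

All curves live in the oblique-sagittal measurement plane (x horizontal,
y vertical, z = 0); lengths are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Line",
    "Arc",
    "PiecewiseCurve",
    "line_angle_deg",
    "ray_angle_deg",
    "fillet_corner",
]


@dataclass(frozen=True)
class Line:
    p0: np.ndarray
    p1: np.ndarray

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def point(self, s: float | np.ndarray) -> np.ndarray:
        # s is arc length from p0
        t = np.asarray(s, float) / self.length
        return np.outer(np.atleast_1d(t), self.p1 - self.p0) + self.p0


@dataclass(frozen=True)
class Arc:
    """Circular arc from angle a0 to a1 (radians, linear sweep, may be cw)."""

    center: np.ndarray
    radius: float
    a0: float
    a1: float

    @property
    def length(self) -> float:
        return float(self.radius * abs(self.a1 - self.a0))

    def angle_at(self, s: float | np.ndarray):
        return self.a0 + (self.a1 - self.a0) * np.asarray(s, float) / self.length

    def point(self, s: float | np.ndarray) -> np.ndarray:
        a = np.atleast_1d(self.angle_at(s))
        return self.center + self.radius * np.stack([np.cos(a), np.sin(a)], axis=-1)

    def top_y(self) -> float:
        """Maximum y over the arc (exact)."""
        ys = [self.point(0.0)[0, 1], self.point(self.length)[0, 1]]
        # interior candidate: the circle's topmost point at angle pi/2 (mod 2pi)
        lo, hi = sorted((self.a0, self.a1))
        k0 = np.ceil((lo - np.pi / 2) / (2 * np.pi))
        cand = np.pi / 2 + 2 * np.pi * k0
        if lo <= cand <= hi:
            ys.append(self.center[1] + self.radius)
        return float(max(ys))

    def s_of_angle(self, a: float) -> float:
        return float((a - self.a0) / (self.a1 - self.a0) * self.length)


class PiecewiseCurve:
    """Concatenation of Line/Arc pieces with a global arc-length parameter."""

    def __init__(self, pieces):
        self.pieces = list(pieces)
        lens = np.array([p.length for p in self.pieces])
        if np.any(lens <= 0):
            raise ValueError("degenerate piece with non-positive length")
        self.cum = np.concatenate([[0.0], np.cumsum(lens)])

    @property
    def length(self) -> float:
        return float(self.cum[-1])

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, float))
        out = np.empty((len(s), 2))
        idx = np.clip(np.searchsorted(self.cum, s, side="right") - 1, 0, len(self.pieces) - 1)
        for i in np.unique(idx):
            m = idx == i
            local = np.clip(s[m] - self.cum[i], 0.0, self.pieces[i].length)
            out[m] = self.pieces[i].point(local)
        return out

    def knots(self) -> np.ndarray:
        return self.cum.copy()


def line_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Acute intersection angle between two undirected lines, degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def ray_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two rays (direction vectors), in [0, 180] degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def fillet_corner(e0: np.ndarray, c: np.ndarray, e1: np.ndarray, r: float):
    """Fillet the corner c of the polyline e0-c-e1 with a circle of radius r.

    Returns (t0, arc, t1): tangent points on each leg and the connecting Arc
    traversed from t0 to t1. Raises ValueError when the tangent length exceeds
    either leg.
    """
    u0 = (e0 - c) / np.linalg.norm(e0 - c)
    u1 = (e1 - c) / np.linalg.norm(e1 - c)
    cos_t = np.clip(np.dot(u0, u1), -1.0, 1.0)
    theta = np.arccos(cos_t)  # corner opening angle
    if theta < 1e-9 or theta > np.pi - 1e-9:
        raise ValueError("corner is degenerate (collinear legs)")
    tan_len = r / np.tan(theta / 2.0)
    if tan_len >= 0.95 * min(np.linalg.norm(e0 - c), np.linalg.norm(e1 - c)):
        raise ValueError("fillet radius too large for the corner legs")
    bis = u0 + u1
    bis /= np.linalg.norm(bis)
    center = c + bis * (r / np.sin(theta / 2.0))
    t0 = c + u0 * tan_len
    t1 = c + u1 * tan_len
    a0 = float(np.arctan2(*(t0 - center)[::-1]))
    a1 = float(np.arctan2(*(t1 - center)[::-1]))
    # choose the sweep (<= pi) from a0 to a1
    da = (a1 - a0 + np.pi) % (2 * np.pi) - np.pi
    arc = Arc(center=center, radius=r, a0=a0, a1=a0 + da)
    return t0, arc, t1
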