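"""3D reconstruction of the organ from its per-segment curvature state.

The organ's shape is fully determined by the per-segment ``(rest_length,
C, psi_c)`` data once a frame is fixed at the base.  The reference
director ``d1`` (the phi = 0 direction of the cross-section) is
transported with *zero twist* about the tangent — the frame analogue of
the no-material-torsion assumption (lines drawn on the surface parallel
to the axis stay parallel).  Within each segment the curvature is
constant, so frames and positions are propagated by the exact
constant-curvature arc rotation; discretization error is purely an
effect of the segmentation in s.

Conventions: gravity axis +z, base clamped at the origin with tangent
+z and director +x; the "horizontal plane" is (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import OrganState, surface_segment_length

__all__ = [
    "Centerline3D",
    "ApicalTrack",
    "reconstruct_centerline",
    "apical_tip",
    "track_tip",
    "planarity_deviation",
    "surface_fiber_lengths",
]


@dataclass
class Centerline3D:
    """Reconstructed median line: positions plus an adapted, twist-free frame.

    ``points``, ``tangents`` and ``directors`` have one row per segment
    boundary (n_segments + 1).  ``directors`` is the phi = 0 reference
    direction d1; d2 = tangent x d1 completes the cross-section frame.
    """

    points: np.ndarray
    tangents: np.ndarray
    directors: np.ndarray

    def __post_init__(self):
        for name in ("points", "tangents", "directors"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (n, 3)")
            setattr(self, name, arr)

    @property
    def d2(self) -> np.ndarray:
        return np.cross(self.tangents, self.directors)

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class ApicalTrack:
    """Horizontal-plane trajectory of the apical tip."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError("times, x, y must share a shape")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def theta(self) -> np.ndarray:
        """Polar angle, unwrapped along the track."""
        return np.unwrap(np.arctan2(self.y, self.x))

    def rotated(self, alpha: float) -> "ApicalTrack":
        """The same track rotated rigidly by alpha about the origin."""
        c, s = np.cos(alpha), np.sin(alpha)
        return ApicalTrack(
            self.times, c * self.x - s * self.y, s * self.x + c * self.y
        )


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def reconstruct_centerline(
    organ: OrganState, base_azimuth: float = 0.0
) -> Centerline3D:
    """Integrate the twist-free frame along the organ's segments.

    Each segment is a circular arc of curvature ``C`` bending toward the
    cross-section direction ``psi_c`` (measured from d1 at the segment's
    base).  The frame is rotated by the exact arc rotation about the
    local binormal, which transports (d1, d2) without twist.

    ``base_azimuth`` rotates the base director about +z (gauge freedom of
    the phi = 0 reference); the reconstructed shape rotates rigidly.
    """
    n = organ.n_segments
    points = np.empty((n + 1, 3))
    tangents = np.empty((n + 1, 3))
    directors = np.empty((n + 1, 3))
    p = np.zeros(3)
    t = np.array([0.0, 0.0, 1.0])
    ca, sa = np.cos(base_azimuth), np.sin(base_azimuth)
    d1 = np.array([ca, sa, 0.0])
    points[0], tangents[0], directors[0] = p, t, d1

    ells = organ.rest_lengths
    curvs = organ.curvatures
    psis = organ.psi_cs
    for i in range(n):
        ell, C, psi = ells[i], curvs[i], psis[i]
        if C * ell < 1e-12:
            p = p + ell * t
        else:
            d2 = np.cross(t, d1)
            nvec = np.cos(psi) * d1 + np.sin(psi) * d2  # toward the bend
            theta = C * ell
            p = p + (np.sin(theta) / C) * t + ((1.0 - np.cos(theta)) / C) * nvec
            rot = _rodrigues(np.cross(t, nvec), theta)
            t = rot @ t
            d1 = rot @ d1
            # guard against slow drift of orthonormality
            t /= np.linalg.norm(t)
            d1 -= np.dot(d1, t) * t
            d1 /= np.linalg.norm(d1)
        points[i + 1], tangents[i + 1], directors[i + 1] = p, t, d1
    return Centerline3D(points, tangents, directors)


def apical_tip(organ: OrganState, base_azimuth: float = 0.0) -> np.ndarray:
    """3D position (x_a, y_a, z_a) of the apex; (x_a, y_a) is the
    horizontal projection tracked in experiments."""
    return reconstruct_centerline(organ, base_azimuth).tip


def track_tip(states: Sequence[OrganState]) -> ApicalTrack:
    """Assemble the horizontal apical track from a sequence of organ states."""
    if len(states) < 2:
        raise ValueError("need at least two states")
    times = np.array([st.time for st in states])
    if not np.all(np.diff(times) > 0):
        raise ValueError("state times must be strictly increasing")
    tips = np.array([apical_tip(st) for st in states])
    return ApicalTrack(times, tips[:, 0], tips[:, 1])


def planarity_deviation(line: Centerline3D) -> float:
    """Out-of-plane extent of the centerline, normalized by its length.

    Smallest singular value of the centered point cloud divided by the
    total arc length: 0 for planar shapes, positive for helical ones.
    """
    pts = line.points
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    arclen = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return float(sv[-1] / arclen) if arclen > 0 else 0.0


def surface_fiber_lengths(
    line: Centerline3D, organ: OrganState, phi: float
) -> np.ndarray:
    """Per-segment length of the surface fiber at cross-section angle phi,
    measured on the reconstructed geometry.

    Within a segment the fiber is itself a circular arc about the
    segment's bending axis.  Everything is read off the reconstructed
    geometry alone: the arc angle from consecutive tangents, the bending
    direction and radius from the chord, the fiber offset from the local
    frame.  Should agree with :func:`nutkin.core.surface_segment_length`
    to machine precision, making this an independent consistency check of
    the reconstruction.
    """
    out = np.empty(organ.n_segments)
    R = organ.radius
    for i in range(organ.n_segments):
        p = line.points[i]
        t = line.tangents[i]
        d1 = line.directors[i]
        d2 = np.cross(t, d1)
        radial = np.cos(phi) * d1 + np.sin(phi) * d2
        chord = line.points[i + 1] - p
        t_next = line.tangents[i + 1]
        theta = np.arctan2(np.linalg.norm(np.cross(t, t_next)), np.dot(t, t_next))
        if theta < 1e-9:
            # straight segment: fiber parallel to the median line
            out[i] = float(np.linalg.norm(chord))
            continue
        nvec = chord - np.dot(chord, t) * t
        nvec /= np.linalg.norm(nvec)  # toward the bend
        arc_radius = np.linalg.norm(chord) / (2.0 * np.sin(theta / 2.0))
        center = p + arc_radius * nvec
        axis = np.cross(t, nvec)  # bending axis direction (unit)
        fiber_pt = p + R * radial
        rel = fiber_pt - center
        dist = np.linalg.norm(rel - np.dot(rel, axis) * axis)
        out[i] = theta * dist
    return out
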