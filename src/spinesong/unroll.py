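"""Straightening / unrolling of spine positions around the medial axis.

Each spine's 3D insertion point is reduced to two cylindrical coordinates
relative to the dendrite's medial axis: the arc-length position ``s`` of its
orthogonal projection onto the axis polyline, and the angle ``theta`` of the
radial offset measured in a moving orthonormal frame carried along the axis.
This is the planar "unrolled" arrangement the sonification scans through.

Frames are rotation-minimizing (propagated by the double-reflection method),
not Frenet frames: Frenet frames are undefined on straight segments and flip
at inflection points, which would scramble ``theta`` for realistic traced
axes.  The angular origin is set by a user-supplied reference direction
(default ``(1, 0, 0)``) orthogonalized against the first tangent; ``theta``
increases counter-clockwise about the tangent in the right-handed frame
(t, n, b), i.e. ``theta = atan2(r·b, r·n)`` mapped to [0, 360).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import MedialAxis, SpineRecord

__all__ = [
    "AxisFrameSet",
    "UnrolledSpine",
    "project_to_axis",
    "compute_frames",
    "frame_at",
    "unroll_spines",
    "write_unrolled_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AxisFrameSet:
    """Per-vertex orthonormal frames (tangent, normal, binormal) of an axis."""

    tangents: np.ndarray  # (n, 3)
    normals: np.ndarray  # (n, 3)
    binormals: np.ndarray  # (n, 3)


@dataclass(frozen=True)
class UnrolledSpine:
    """A spine in straightened coordinates: (s along axis, theta around it)."""

    spine_id: str
    s: float  # μm, in [0, total axis length]
    theta: float  # degrees, in [0, 360)
    radial_dist: float  # μm
    length_um: float
    volume_um3: float


def _vertex_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each vertex: edge direction at ends, angle-bisecting
    average of adjacent edge directions in the interior."""
    edges = np.diff(points, axis=0)
    edirs = edges / np.linalg.norm(edges, axis=1, keepdims=True)
    t = np.empty_like(points)
    t[0] = edirs[0]
    t[-1] = edirs[-1]
    if len(points) > 2:
        mid = edirs[:-1] + edirs[1:]
        t[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    return t


def compute_frames(axis: MedialAxis, reference_dir=(1.0, 0.0, 0.0)) -> AxisFrameSet:
    """Rotation-minimizing frames along the axis via double reflection.

    The first normal is ``reference_dir`` orthogonalized against the first
    tangent; subsequent frames are propagated with the double-reflection
    update, which transports the normal with no spurious twist (a straight
    axis yields identical frames at every vertex).

    Raises
    ------
    ValueError
        If ``reference_dir`` is parallel to the first tangent; choose
        another reference direction in that case.
    """
    pts = axis.points
    t = _vertex_tangents(pts)
    ref = np.asarray(reference_dir, dtype=float)
    nrm = np.linalg.norm(ref)
    if nrm == 0:
        raise ValueError("reference_dir must be non-zero")
    ref = ref / nrm
    n0 = ref - np.dot(ref, t[0]) * t[0]
    if np.linalg.norm(n0) < 1e-12:
        raise ValueError(
            "reference_dir is parallel to the first tangent; supply a different reference direction"
        )
    n0 /= np.linalg.norm(n0)

    n = np.empty_like(t)
    n[0] = n0
    for i in range(len(pts) - 1):
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        r_l = n[i] - (2.0 / c1) * np.dot(v1, n[i]) * v1
        t_l = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - t_l
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            n[i + 1] = r_l
        else:
            n[i + 1] = r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
        # guard against fp drift: re-orthogonalize and renormalize
        n[i + 1] -= np.dot(n[i + 1], t[i + 1]) * t[i + 1]
        n[i + 1] /= np.linalg.norm(n[i + 1])
    b = np.cross(t, n)
    return AxisFrameSet(tangents=t, normals=n, binormals=b)


def project_to_axis(point, axis: MedialAxis) -> tuple[float, np.ndarray]:
    """Orthogonal projection of a point onto the axis polyline.

    Returns the arc-length coordinate ``s`` of the closest point on the
    polyline (interpolated within segments) and the radial vector
    ``point - closest_point``.  Distance ties are broken toward smaller
    ``s``.
    """
    p = np.asarray(point, dtype=float)
    a = axis.points[:-1]
    d = np.diff(axis.points, axis=0)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    u = np.clip(np.einsum("ij,ij->i", p - a, d) / seg_len2, 0.0, 1.0)
    feet = a + u[:, None] * d
    dist2 = np.einsum("ij,ij->i", p - feet, p - feet)
    i = int(np.argmin(dist2))  # argmin returns the first minimum: smallest s wins
    s = float(axis.cum_s[i] + u[i] * np.sqrt(seg_len2[i]))
    return s, p - feet[i]


def frame_at(axis: MedialAxis, frames: AxisFrameSet, s: float):
    """Interpolated (point, tangent, normal, binormal) at arc position ``s``.

    Within a segment the tangent is the segment direction; the normal is the
    linear interpolation of the vertex normals, re-orthogonalized against
    the tangent and normalized; the binormal closes the right-handed triad.
    """
    cs = axis.cum_s
    s = float(np.clip(s, 0.0, cs[-1]))
    i = int(np.searchsorted(cs, s, side="right") - 1)
    i = min(max(i, 0), len(cs) - 2)
    seg = cs[i + 1] - cs[i]
    u = (s - cs[i]) / seg
    point = (1 - u) * axis.points[i] + u * axis.points[i + 1]
    t = axis.points[i + 1] - axis.points[i]
    t = t / np.linalg.norm(t)
    n = (1 - u) * frames.normals[i] + u * frames.normals[i + 1]
    n = n - np.dot(n, t) * t
    n = n / np.linalg.norm(n)
    b = np.cross(t, n)
    return point, t, n, b


def unroll_spines(
    spines: list[SpineRecord], axis: MedialAxis, frames: AxisFrameSet | None = None
) -> list[UnrolledSpine]:
    """Map each spine to straightened coordinates (s, theta, radial_dist).

    Input order is preserved.  A spine whose insertion point lies exactly on
    the axis has no defined angle; ``theta`` is set to 0 and a warning is
    logged.
    """
    if frames is None:
        frames = compute_frames(axis)
    out = []
    for sp in spines:
        s, radial = project_to_axis(sp.insertion, axis)
        r = float(np.linalg.norm(radial))
        if r == 0.0:
            logger.warning("spine %s inserts exactly on the axis; theta set to 0", sp.spine_id)
            theta = 0.0
        else:
            _, _, n, b = frame_at(axis, frames, s)
            theta = float(np.degrees(np.arctan2(np.dot(radial, b), np.dot(radial, n))) % 360.0)
        out.append(
            UnrolledSpine(
                spine_id=sp.spine_id,
                s=s,
                theta=theta,
                radial_dist=r,
                length_um=sp.length_um,
                volume_um3=sp.volume_um3,
            )
        )
    return out


def write_unrolled_csv(unrolled: list[UnrolledSpine], path) -> None:
    """Export unrolled coordinates as CSV."""
    df = pd.DataFrame(
        {
            "spine_id": [u.spine_id for u in unrolled],
            "s_um": [u.s for u in unrolled],
            "theta_deg": [u.theta for u in unrolled],
            "radial_dist_um": [u.radial_dist for u in unrolled],
            "length_um": [u.length_um for u in unrolled],
            "volume_um3": [u.volume_um3 for u in unrolled],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
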