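"""Measurement operators over 3D centerlines.

These emulate, on explicit point paths, the measurements a morphologist
takes on a rendered endocast: fitting a plane to a semicircular canal,
reading the arc's height and width, quantifying its departure from
planarity, angles between canal planes, the coiling and profile of the
cochlear spiral, and the sagittal labyrinthine index.

Conventions (chosen for determinism; see the methods note):

* canal planes are total-least-squares fits (minimum summed squared
  orthogonal distance) over the full centerline;
* "total linear deviation" is the range (max - min) of signed orthogonal
  distances from the fitted plane, so a symmetric sinusoidal warp of
  amplitude A measures 2A;
* in-plane height/width are extents along the principal axes of the
  projected points (width = major axis);
* coiling is the cumulative unwrapped azimuth about the spiral axis,
  referenced to the basal-most point.

All operators are invariant under rigid motions; lengths scale linearly
and angles are invariant under uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Centerline:
    """An ordered 3D point path (mm) along a canal or cochlear spiral."""

    points: np.ndarray  # (n, 3)
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 8:
            raise ValueError("a centerline needs at least 8 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive points must be distinct")


@dataclass
class PlaneFit:
    normal: np.ndarray  # unit vector
    centroid: np.ndarray
    rms_residual_mm: float

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.centroid) @ self.normal


def fit_plane(centerline: Centerline) -> PlaneFit:
    """Total-least-squares plane through a centerline.

    The normal is the singular direction of least variance; degenerate
    (collinear) inputs are rejected.
    """
    pts = centerline.points
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # collinear: second singular value vanishes relative to the first
    if s[0] == 0 or s[1] / s[0] < 1e-10:
        raise ValueError("centerline is collinear; no unique plane")
    normal = vt[2]
    resid = centred @ normal
    return PlaneFit(
        normal=normal,
        centroid=centroid,
        rms_residual_mm=float(np.sqrt(np.mean(resid**2))),
    )


def _inplane_coords(centerline: Centerline, plane: PlaneFit) -> np.ndarray:
    """Project points into the plane and rotate onto its principal axes
    (first axis = direction of larger in-plane variance)."""
    centred = centerline.points - plane.centroid
    inplane = centred - np.outer(centred @ plane.normal, plane.normal)
    # principal axes of the projected cloud
    _, s, vt = np.linalg.svd(inplane, full_matrices=False)
    if s[1] / s[0] < 1e-12:
        raise ValueError("degenerate projection")
    return inplane @ vt[:2].T


def arc_extents(centerline: Centerline, plane: PlaneFit) -> tuple[float, float]:
    """(height, width) of a canal arc within its plane.

    Width is the extent along the major in-plane principal axis, height the
    extent along the minor one; no height <= width convention is imposed
    beyond that axis ordering.
    """
    uv = _inplane_coords(centerline, plane)
    width = float(uv[:, 0].max() - uv[:, 0].min())
    height = float(uv[:, 1].max() - uv[:, 1].min())
    return height, width


def linear_deviation(centerline: Centerline, plane: PlaneFit) -> float:
    """Total linear deviation: the range of signed distances to the plane."""
    d = plane.signed_distances(centerline.points)
    return float(d.max() - d.min())


def interplane_angle(
    plane1: PlaneFit, plane2: PlaneFit, reference_point: np.ndarray
) -> float:
    """Angle (degrees, in [0, 180]) between two canal planes.

    Both normals are first oriented toward the side of ``reference_point``
    (the labyrinth centroid); the angle between the oriented normals is
    reported.  This convention makes obtuse inter-canal angles meaningful.
    """
    ref = np.asarray(reference_point, dtype=float)
    n1, n2 = plane1.normal.copy(), plane2.normal.copy()
    if np.dot(n1, ref - plane1.centroid) < 0:
        n1 = -n1
    if np.dot(n2, ref - plane2.centroid) < 0:
        n2 = -n2
    cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _azimuths(centerline: Centerline, axis_point, axis_direction) -> np.ndarray:
    """Unwrapped azimuth (radians) of each point about the axis."""
    k = np.asarray(axis_direction, dtype=float)
    k = k / np.linalg.norm(k)
    rel = centerline.points - np.asarray(axis_point, dtype=float)
    radial = rel - np.outer(rel @ k, k)
    r = np.linalg.norm(radial, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("centerline touches the rotation axis")
    # orthonormal in-plane basis
    u = radial[0] / r[0]
    v = np.cross(k, u)
    az = np.arctan2(radial @ v, radial @ u)
    return np.unwrap(az)


def cochlear_coiling(centerline: Centerline, axis_point, axis_direction) -> float:
    """Total coiling (degrees) of a spiral about its axis.

    The cumulative unwrapped polar angle from the azimuth of the first
    (basal-most) point to the last; independent of traversal direction.
    """
    az = _azimuths(centerline, axis_point, axis_direction)
    return float(abs(np.degrees(az[-1] - az[0])))


def cochlear_profile(
    centerline: Centerline, axis_point, axis_direction
) -> tuple[float, float, float, bool]:
    """(height, basal width, aspect ratio, full_basal_turn) of a spiral.

    Height is the extent along the axis; basal width the maximal diameter
    (largest pairwise distance perpendicular to the axis) over the first
    360 degrees of coil.  If the spiral completes less than one turn the
    width is taken over the available arc and flagged.
    """
    k = np.asarray(axis_direction, dtype=float)
    k = k / np.linalg.norm(k)
    heights = centerline.points @ k
    height = float(heights.max() - heights.min())
    az = _azimuths(centerline, axis_point, axis_direction)
    swept = np.abs(az - az[0])
    basal = centerline.points[swept <= 2 * np.pi + 1e-9]
    full_turn = bool(swept.max() >= 2 * np.pi - 1e-9)
    rel = basal - np.asarray(axis_point, dtype=float)
    proj = rel - np.outer(rel @ k, k)
    # maximal pairwise separation perpendicular to the axis
    diff = proj[:, None, :] - proj[None, :, :]
    width = float(np.sqrt((diff**2).sum(axis=2)).max())
    aspect = height / width if width > 0 else float("inf")
    if width == 0:
        raise ValueError("degenerate basal turn (zero width)")
    return height, width, aspect, full_turn


def sagittal_index(
    posterior_centerline: Centerline, lateral_plane: PlaneFit, dorsal_direction
) -> float:
    """Percent of the posterior canal arc's span below the lateral plane.

    "Below" is the side of the lateral-canal plane opposite the supplied
    dorsal direction.  Returns a value in [0, 100]; 0 when the whole arc
    sits above the plane.
    """
    dorsal = np.asarray(dorsal_direction, dtype=float)
    normal = lateral_plane.normal
    if np.dot(normal, dorsal) < 0:
        normal = -normal  # orient the normal dorsally
    d = (posterior_centerline.points - lateral_plane.centroid) @ normal
    span = d.max() - d.min()
    if span <= 0:
        return 0.0
    below = min(d.max(), 0.0) - d.min()
    return float(100.0 * max(below, 0.0) / span)
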