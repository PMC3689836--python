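"""Parametric synthetic labyrinths with known ground truth.

Stands in for CT endocasts: every quantity the geometry operators measure
(arc radius, aspect, plane orientation, planarity deviation, coiling,
spiral profile) is generated from explicit parameters, so measurement
pipelines can be validated against truth.

A canal is an ellipse of given radius/aspect lying in a given plane,
optionally warped out of plane by a single-frequency sinusoid
``A sin(k t)`` (for k >= 2 over a full circle the warp is orthogonal to the
plane's harmonics, so the best-fit plane stays put and the realized total
linear deviation is exactly 2A).  A cochlea is a conical helix whose
azimuth sweeps the requested coil, radius shrinking linearly per turn and
height rising linearly.  Isotropic Gaussian noise of chosen sd may be
added; generation is deterministic for a fixed seed.

Named presets (didelphis_like, cavia_like, tursiops_like) put the
parameters at the scale of exemplar taxa in the comparative tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import Centerline


@dataclass
class CanalSpec:
    arc_radius_mm: float = 1.0
    aspect: float = 1.0  # height / width of the arc ellipse
    normal: tuple = (0.0, 0.0, 1.0)
    arc_fraction: float = 1.0  # fraction of a full circle
    warp_amplitude_mm: float = 0.0
    warp_cycles: int = 2
    n_points: int = 512

    def __post_init__(self) -> None:
        if self.arc_radius_mm <= 0:
            raise ValueError("arc radius must be positive")
        if not 0 < self.arc_fraction <= 1:
            raise ValueError("arc fraction must lie in (0, 1]")
        if self.n_points < 8:
            raise ValueError("need at least 8 points")


@dataclass
class CochleaSpec:
    coil_degrees: float = 790.0
    basal_radius_mm: float = 1.0
    taper_per_turn_mm: float = 0.25
    height_mm: float = 1.2
    n_points: int = 1024

    def __post_init__(self) -> None:
        if self.coil_degrees <= 0:
            raise ValueError("coil must be positive")
        turns = self.coil_degrees / 360.0
        if self.basal_radius_mm - self.taper_per_turn_mm * turns <= 0:
            raise ValueError("taper drives the spiral radius negative")
        if self.n_points < 8:
            raise ValueError("need at least 8 points")


@dataclass
class LabyrinthSpec:
    """Full synthetic labyrinth: three canals at specified mutual plane
    angles plus a cochlea at a given basal angle to the lateral canal."""

    anterior: CanalSpec = field(default_factory=lambda: CanalSpec(arc_radius_mm=1.46))
    lateral: CanalSpec = field(default_factory=lambda: CanalSpec(arc_radius_mm=0.88))
    posterior: CanalSpec = field(default_factory=lambda: CanalSpec(arc_radius_mm=1.23))
    angle_AL_deg: float = 90.0
    angle_AP_deg: float = 90.0
    angle_LP_deg: float = 90.0
    cochlea: CochleaSpec = field(default_factory=CochleaSpec)
    cochlea_basal_angle_deg: float = 20.0
    canal_offset_mm: float = 2.0  # canal centres sit this far from the hub
    noise_sd_mm: float = 0.0
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Realized ground truth for one generated object or bundle."""

    arc_radius_mm: Optional[float] = None
    arc_height_mm: Optional[float] = None
    arc_width_mm: Optional[float] = None
    aspect: Optional[float] = None
    normal: Optional[np.ndarray] = None
    plane_point: Optional[np.ndarray] = None
    arc_length_mm: Optional[float] = None
    linear_deviation_mm: Optional[float] = None
    coil_degrees: Optional[float] = None
    turns: Optional[float] = None
    height_mm: Optional[float] = None
    basal_width_mm: Optional[float] = None
    axis_point: Optional[np.ndarray] = None
    axis_direction: Optional[np.ndarray] = None
    angles: Optional[dict] = None  # pairwise inter-plane angles
    reference_point: Optional[np.ndarray] = None


def _orthonormal_frame(normal) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = np.asarray(normal, dtype=float)
    k = k / np.linalg.norm(k)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, k)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(k, helper)
    u /= np.linalg.norm(u)
    v = np.cross(k, u)
    return u, v, k


def generate_canal(
    spec: CanalSpec,
    seed: int = 0,
    center=(0.0, 0.0, 0.0),
    noise_sd_mm: float = 0.0,
) -> tuple[Centerline, SyntheticTruth]:
    """Generate one semicircular-canal centerline with its ground truth."""
    rng = np.random.default_rng(seed)
    u, v, k = _orthonormal_frame(spec.normal)
    # semi-axes from radius R = (h + w)/4 and aspect q = h/w
    a = 2.0 * spec.arc_radius_mm / (1.0 + spec.aspect)  # semi-major (width/2)
    b = a * spec.aspect
    t = np.linspace(0.0, 2.0 * np.pi * spec.arc_fraction, spec.n_points,
                    endpoint=spec.arc_fraction < 1.0)
    c = np.asarray(center, dtype=float)
    pts = (
        c
        + np.outer(a * np.cos(t), u)
        + np.outer(b * np.sin(t), v)
        + np.outer(spec.warp_amplitude_mm * np.sin(spec.warp_cycles * t), k)
    )
    if noise_sd_mm > 0:
        pts = pts + rng.normal(0.0, noise_sd_mm, pts.shape)
    # ellipse perimeter along the generated fraction (numeric arc length)
    dense = np.linspace(0, 2 * np.pi * spec.arc_fraction, 4096)
    seg = np.hypot(a * np.diff(np.cos(dense)), b * np.diff(np.sin(dense)))
    truth = SyntheticTruth(
        arc_radius_mm=spec.arc_radius_mm,
        arc_height_mm=2 * b,
        arc_width_mm=2 * a,
        aspect=spec.aspect,
        normal=k,
        plane_point=c,
        arc_length_mm=float(seg.sum()),
        linear_deviation_mm=(
            2.0 * spec.warp_amplitude_mm if spec.warp_cycles >= 2 else None
        ),
    )
    return Centerline(pts, closed=spec.arc_fraction == 1.0), truth


def generate_cochlea(
    spec: CochleaSpec,
    seed: int = 0,
    apex=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    noise_sd_mm: float = 0.0,
) -> tuple[Centerline, SyntheticTruth]:
    """Generate a conical-helix cochlear centerline (base -> apex)."""
    rng = np.random.default_rng(seed)
    u, v, k = _orthonormal_frame(axis)
    theta = np.linspace(0.0, np.radians(spec.coil_degrees), spec.n_points)
    radius = spec.basal_radius_mm - spec.taper_per_turn_mm * theta / (2 * np.pi)
    height = spec.height_mm * theta / theta[-1]
    base = np.asarray(apex, dtype=float) - spec.height_mm * k
    pts = (
        base
        + np.outer(radius * np.cos(theta), u)
        + np.outer(radius * np.sin(theta), v)
        + np.outer(height, k)
    )
    if noise_sd_mm > 0:
        pts = pts + rng.normal(0.0, noise_sd_mm, pts.shape)
    # realized basal width: widest diameter across the first full turn
    if spec.coil_degrees >= 360:
        width = spec.basal_radius_mm + (
            spec.basal_radius_mm - spec.taper_per_turn_mm / 2.0
        )
    else:
        width = None
    truth = SyntheticTruth(
        coil_degrees=spec.coil_degrees,
        turns=spec.coil_degrees / 360.0,
        height_mm=spec.height_mm,
        basal_width_mm=width,
        aspect=(spec.height_mm / width) if width else None,
        axis_point=np.asarray(apex, dtype=float),
        axis_direction=k,
    )
    return Centerline(pts, closed=False), truth


def _canal_normals(al_deg: float, ap_deg: float, lp_deg: float) -> dict:
    """Unit normals realizing the requested pairwise plane angles, or raise
    if no such triple of directions exists."""
    al, ap, lp = map(np.radians, (al_deg, ap_deg, lp_deg))
    n_lat = np.array([0.0, 0.0, 1.0])
    n_ant = np.array([np.sin(al), 0.0, np.cos(al)])
    z = np.cos(lp)
    x = (np.cos(ap) - np.cos(lp) * np.cos(al)) / np.sin(al)
    rest = 1.0 - x * x - z * z
    if rest < -1e-12:
        raise ValueError("no orientation realizes the requested angle triple")
    y = np.sqrt(max(rest, 0.0))
    n_post = np.array([x, y, z])
    return {"anterior": n_ant, "lateral": n_lat, "posterior": n_post}


def generate_labyrinth(spec: LabyrinthSpec) -> tuple[dict, SyntheticTruth]:
    """Generate the 3-canal + cochlea bundle.

    Canal centres are placed a fixed offset from a common hub along their
    plane normals, so orienting fitted normals toward the bundle centroid
    recovers the requested inter-plane angles.  Returns a dict of named
    centerlines and the bundle truth (pairwise angles, reference point,
    per-part truths attached as ``truth.angles`` etc.).
    """
    normals = _canal_normals(spec.angle_AL_deg, spec.angle_AP_deg, spec.angle_LP_deg)
    hub = np.zeros(3)
    parts: dict[str, Centerline] = {}
    part_truths: dict[str, SyntheticTruth] = {}
    for i, (name, cspec) in enumerate(
        (("anterior", spec.anterior), ("lateral", spec.lateral),
         ("posterior", spec.posterior))
    ):
        cspec = replace(cspec, normal=tuple(normals[name]))
        center = hub + spec.canal_offset_mm * normals[name]
        line, truth = generate_canal(
            cspec, seed=spec.seed + i, center=center, noise_sd_mm=spec.noise_sd_mm
        )
        parts[name] = line
        part_truths[name] = truth
    # cochlea: basal-turn plane tilted from the lateral plane by the basal angle
    ang = np.radians(spec.cochlea_basal_angle_deg)
    axis = np.array([np.sin(ang), 0.0, np.cos(ang)])
    apex = hub - 2.0 * spec.canal_offset_mm * axis
    line, truth = generate_cochlea(
        spec.cochlea, seed=spec.seed + 3, apex=apex, axis=axis,
        noise_sd_mm=spec.noise_sd_mm,
    )
    parts["cochlea"] = line
    part_truths["cochlea"] = truth

    def pair(u, v):
        return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1))))

    bundle = SyntheticTruth(
        angles={
            ("anterior", "lateral"): pair(normals["anterior"], normals["lateral"]),
            ("anterior", "posterior"): pair(normals["anterior"], normals["posterior"]),
            ("lateral", "posterior"): pair(normals["lateral"], normals["posterior"]),
            ("cochlea", "lateral"): pair(axis, normals["lateral"]),
        },
        reference_point=hub,
    )
    bundle.parts = part_truths  # type: ignore[attr-defined]
    return parts, bundle


# -- presets at the scale of exemplar taxa ----------------------------------

def didelphis_like(noise_sd_mm: float = 0.0, seed: int = 0) -> LabyrinthSpec:
    """Opossum-scale labyrinth: anterior canal largest, obtuse A-L angle,
    ~2.2-turn moderately high cochlea."""
    return LabyrinthSpec(
        anterior=CanalSpec(arc_radius_mm=1.46, aspect=0.97, warp_amplitude_mm=0.11),
        lateral=CanalSpec(arc_radius_mm=0.88, aspect=0.79, warp_amplitude_mm=0.19),
        posterior=CanalSpec(arc_radius_mm=1.23, aspect=1.08, warp_amplitude_mm=0.0),
        angle_AL_deg=109.0, angle_AP_deg=102.0, angle_LP_deg=104.0,
        cochlea=CochleaSpec(coil_degrees=791.0, basal_radius_mm=1.1,
                            taper_per_turn_mm=0.28, height_mm=1.28),
        cochlea_basal_angle_deg=19.6,
        noise_sd_mm=noise_sd_mm, seed=seed,
    )


def cavia_like(noise_sd_mm: float = 0.0, seed: int = 0) -> LabyrinthSpec:
    """Guinea-pig-scale labyrinth: >4 cochlear turns, high spire."""
    return LabyrinthSpec(
        anterior=CanalSpec(arc_radius_mm=1.88, aspect=0.75, warp_amplitude_mm=0.31),
        lateral=CanalSpec(arc_radius_mm=1.57, aspect=0.49, warp_amplitude_mm=0.21),
        posterior=CanalSpec(arc_radius_mm=1.63, aspect=0.99, warp_amplitude_mm=0.43),
        angle_AL_deg=77.2, angle_AP_deg=105.0, angle_LP_deg=85.5,
        cochlea=CochleaSpec(coil_degrees=1457.0, basal_radius_mm=1.0,
                            taper_per_turn_mm=0.18, height_mm=2.3),
        cochlea_basal_angle_deg=35.1,
        noise_sd_mm=noise_sd_mm, seed=seed,
    )


def tursiops_like(noise_sd_mm: float = 0.0, seed: int = 0) -> LabyrinthSpec:
    """Dolphin-scale labyrinth: lateral canal largest, planar canals,
    sub-two-turn flat cochlea."""
    return LabyrinthSpec(
        anterior=CanalSpec(arc_radius_mm=1.19, aspect=0.95, warp_amplitude_mm=0.0),
        lateral=CanalSpec(arc_radius_mm=1.36, aspect=0.96, warp_amplitude_mm=0.1),
        posterior=CanalSpec(arc_radius_mm=0.84, aspect=1.0, warp_amplitude_mm=0.0),
        angle_AL_deg=52.2, angle_AP_deg=84.9, angle_LP_deg=77.5,
        cochlea=CochleaSpec(coil_degrees=661.0, basal_radius_mm=1.6,
                            taper_per_turn_mm=0.5, height_mm=1.5),
        cochlea_basal_angle_deg=21.3,
        noise_sd_mm=noise_sd_mm, seed=seed,
    )
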