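"""Phantom, seed and dosimeter geometry.

The reference layout is a water-filled PMMA cylinder (18 cm diameter,
16 cm long, 2 mm wall) with two ^125I seeds at r = 1.5 cm, theta = 90 and
270 degrees.  Glass rod dosimeters (GRDs, 1.5 mm diameter x 12 mm) sit in
triplets on the outer surface at eight azimuths phi (phi = 0 points along
theta = 90, towards seed #1) and singly at eighteen interior positions in
the mid-plane.  All angles are degrees, all lengths cm; the phantom axis
is z and theta is measured in the mid-plane z = 0.
"""
from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PhantomLayout", "SeedPose", "SeedModel", "DetectorSite",
    "reference_layout", "triplet_azimuths", "site_position_cartesian",
    "seed_position_cartesian", "sites_to_frame", "load_seed_model",
    "TRIPLET_HALF_STEP_DEG", "SURFACE_AZIMUTHS_DEG",
]

TRIPLET_HALF_STEP_DEG = 0.9
SURFACE_AZIMUTHS_DEG = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

GRD_DIAMETER_CM = 0.15
GRD_LENGTH_CM = 1.2


@dataclass(frozen=True)
class PhantomLayout:
    outer_radius: float = 9.0
    length: float = 16.0
    wall_thickness: float = 0.2
    wall_material: str = "pmma"
    interior_material: str = "water"
    exterior_material: str = "air"

    def __post_init__(self):
        if not (self.outer_radius > self.wall_thickness > 0):
            raise ValueError("require outer_radius > wall_thickness > 0")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.wall_thickness

    @property
    def inner_half_length(self) -> float:
        return self.length / 2 - self.wall_thickness


@dataclass(frozen=True)
class SeedPose:
    seed_id: str
    r: float
    theta: float
    z: float = 0.0
    axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not 0 <= self.theta < 360:
            raise ValueError("theta must be in [0, 360)")
        n = math.sqrt(sum(a * a for a in self.axis))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")


@dataclass(frozen=True)
class SeedModel:
    """Encapsulated-seed solid model (cylinders coaxial with the seed axis)."""

    capsule_outer_diameter: float
    capsule_length: float
    capsule_wall: float
    capsule_material: str
    core_diameter: float
    core_length: float
    core_material: str

    def __post_init__(self):
        dims = (self.capsule_outer_diameter, self.capsule_length,
                self.capsule_wall, self.core_diameter, self.core_length)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if (self.core_diameter >= self.capsule_outer_diameter - 2 * self.capsule_wall
                or self.core_length >= self.capsule_length - 2 * self.capsule_wall):
            raise ValueError("core must fit inside the capsule")


@dataclass(frozen=True)
class DetectorSite:
    site_id: str
    kind: str  # "surface" | "internal"
    r: float
    theta: float
    z: float = 0.0
    phi: float | None = None  # surface azimuth; None for internal sites
    body_diameter: float = GRD_DIAMETER_CM
    body_length: float = GRD_LENGTH_CM
    material: str = "glass"

    def __post_init__(self):
        if self.kind not in ("surface", "internal"):
            raise ValueError("kind must be 'surface' or 'internal'")
        if self.body_diameter <= 0 or self.body_length <= 0:
            raise ValueError("body dimensions must be positive")


def triplet_azimuths(phi: float) -> tuple[float, float, float]:
    """The three side-by-side GRD azimuths around a nominal surface angle.

    Neighbouring rods in their 2.8 mm casings are 0.9 degrees apart, so the
    triplet sits at (phi - 0.9, phi, phi + 0.9), reduced modulo 360.
    """
    if not 0 <= phi < 360:
        raise ValueError("phi must be in [0, 360)")
    return ((phi - TRIPLET_HALF_STEP_DEG) % 360.0, phi,
            (phi + TRIPLET_HALF_STEP_DEG) % 360.0)


def _surface_theta(phi: float) -> float:
    # phi = 0 corresponds to theta = 90 (towards seed #1)
    return (90.0 + phi) % 360.0


def reference_layout() -> tuple[PhantomLayout, list[SeedPose], list[DetectorSite]]:
    """The two-seed phantom experiment layout.

    Returns the phantom, the two seed poses (r = 1.5 cm, theta = 90/270),
    24 surface GRD sites (8 azimuths x 3 rods) and 18 internal GRD sites
    (r = 2, 4, 6 at theta = 0, 180; r = 4, 6, 8 at theta = 45, 135, 225,
    315), all in the mid-plane with rod axes parallel to the phantom axis.
    """
    layout = PhantomLayout()
    seeds = [SeedPose("seed1", 1.5, 90.0), SeedPose("seed2", 1.5, 270.0)]

    sites: list[DetectorSite] = []
    for phi in SURFACE_AZIMUTHS_DEG:
        lo, mid, hi = triplet_azimuths(phi)
        for tag, p in (("m", lo), ("c", mid), ("p", hi)):
            sites.append(DetectorSite(
                site_id=f"S{int(phi):03d}{tag}", kind="surface",
                r=layout.outer_radius, theta=_surface_theta(p), phi=p))
    for theta in (0.0, 180.0):
        for r in (2.0, 4.0, 6.0):
            sites.append(DetectorSite(
                site_id=f"I{int(r)}t{int(theta):03d}", kind="internal", r=r, theta=theta))
    for theta in (45.0, 135.0, 225.0, 315.0):
        for r in (4.0, 6.0, 8.0):
            sites.append(DetectorSite(
                site_id=f"I{int(r)}t{int(theta):03d}", kind="internal", r=r, theta=theta))
    return layout, seeds, sites


def site_position_cartesian(site: DetectorSite, layout: PhantomLayout) -> np.ndarray:
    """Centre of a detector body in the right-handed phantom frame (cm)."""
    if site.kind == "surface" and not math.isclose(site.r, layout.outer_radius):
        raise ValueError("surface site must lie on the phantom outer radius")
    if site.kind == "internal" and site.r >= layout.outer_radius:
        raise ValueError("internal site must lie inside the phantom")
    t = math.radians(site.theta)
    return np.array([site.r * math.cos(t), site.r * math.sin(t), site.z])


def seed_position_cartesian(seed: SeedPose) -> np.ndarray:
    t = math.radians(seed.theta)
    return np.array([seed.r * math.cos(t), seed.r * math.sin(t), seed.z])


def sites_to_frame(sites: list[DetectorSite]) -> pd.DataFrame:
    """Tabular export: site_id, kind, r_cm, theta_deg, phi_deg, z_cm."""
    return pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "kind": [s.kind for s in sites],
        "r_cm": [s.r for s in sites],
        "theta_deg": [s.theta for s in sites],
        "phi_deg": [s.phi if s.phi is not None else float("nan") for s in sites],
        "z_cm": [s.z for s in sites],
    })


def load_seed_model() -> SeedModel:
    """The packaged model-6711 seed dimensions (editable fixture)."""
    with resources.files("brachyfit.data").joinpath("seed_6711.toml").open("rb") as fh:
        d = tomllib.load(fh)
    return SeedModel(
        capsule_outer_diameter=d["capsule"]["outer_diameter_cm"],
        capsule_length=d["capsule"]["length_cm"],
        capsule_wall=d["capsule"]["wall_cm"],
        capsule_material=d["capsule"]["material"],
        core_diameter=d["core"]["diameter_cm"],
        core_length=d["core"]["length_cm"],
        core_material=d["core"]["material"],
    )
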