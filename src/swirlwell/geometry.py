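"""Well and orbit geometry for the swirling six-well system.

A single well of a 6-well plate is modelled as a cylinder on the platform of an
orbital shaker.  The platform translates in a horizontal circle (it does not
spin), which in the co-moving frame of the well is equivalent to a rotating
horizontal body force of constant magnitude ``A * omega**2`` plus ordinary
gravity.  Cells are seeded either in a central disc (low-magnitude
multidirectional flow, LMMF) or in an outer annulus (high-magnitude uniaxial
flow, HMUF); the two seeded regions are chosen to have nearly equal area.

Coordinate convention (recorded in all file outputs): right-handed, origin at
the well centre, ``theta`` measured counter-clockwise from +x, and the orbit
phase advances counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = [
    "WellGeometry",
    "RegionAreas",
    "body_force",
    "region_areas",
    "classify_region",
    "RPM_TO_RAD_S",
]

#: conversion factor from revolutions per minute to rad/s
RPM_TO_RAD_S = 2.0 * math.pi / 60.0

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class WellGeometry:
    """Physical and kinematic constants of one well on the orbital shaker.

    Lengths are millimetres.  Defaults describe a 6-well plate well
    (radius 17.4 mm, height 10 mm, 1.9 mL medium giving a 2 mm static
    fluid layer) orbited at 150 rpm with a 5 mm orbital radius, filled
    with culture medium (density 1003 kg/m^3, dynamic viscosity
    0.78e-3 Pa*s).  The seeded-region radii are the central disc
    (r <= 10.5 mm) and the outer annulus (13.5 mm <= r <= wall).

    Parameters
    ----------
    well_radius : float
        Inner radius of the cylindrical well, mm.
    well_height : float
        Height of the well, mm.
    fluid_height : float
        Static (non-swirling) depth of the medium, mm.
    orbital_radius : float
        Radius of the shaker orbit, mm.
    angular_velocity : float
        Orbital angular velocity, rad/s.
    dynamic_viscosity : float
        Dynamic viscosity of the medium, Pa*s.
    density : float
        Density of the medium, kg/m^3.
    disc_radius : float
        Outer radius of the centre seeded disc, mm.
    annulus_inner_radius : float
        Inner radius of the edge seeded annulus, mm (its outer boundary
        is the well wall).
    """

    well_radius: float = 17.4
    well_height: float = 10.0
    fluid_height: float = 2.0
    orbital_radius: float = 5.0
    angular_velocity: float = 150.0 * RPM_TO_RAD_S
    dynamic_viscosity: float = 0.78e-3
    density: float = 1003.0
    disc_radius: float = 10.5
    annulus_inner_radius: float = 13.5

    def __post_init__(self) -> None:
        lengths = {
            "well_radius": self.well_radius,
            "well_height": self.well_height,
            "fluid_height": self.fluid_height,
            "orbital_radius": self.orbital_radius,
            "disc_radius": self.disc_radius,
            "annulus_inner_radius": self.annulus_inner_radius,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("dynamic_viscosity and density must be positive")
        if self.angular_velocity < 0:
            raise ValueError("angular_velocity must be non-negative")
        if not self.disc_radius < self.annulus_inner_radius < self.well_radius:
            raise ValueError(
                "require disc_radius < annulus_inner_radius < well_radius, got "
                f"{self.disc_radius}, {self.annulus_inner_radius}, {self.well_radius}"
            )
        if not self.fluid_height < self.well_height:
            raise ValueError("fluid_height must be smaller than well_height")

    @property
    def period(self) -> float:
        """Orbital period ``T = 2*pi/omega`` in seconds."""
        if self.angular_velocity == 0:
            raise ValueError("period undefined for angular_velocity = 0")
        return 2.0 * math.pi / self.angular_velocity

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity ``mu / rho`` in m^2/s."""
        return self.dynamic_viscosity / self.density

    @classmethod
    def from_rpm(cls, rpm: float, **kwargs) -> "WellGeometry":
        """Build a geometry with the orbit speed given in rpm."""
        return cls(angular_velocity=rpm * RPM_TO_RAD_S, **kwargs)


def body_force(t, geometry: WellGeometry) -> np.ndarray:
    """Acceleration of the translating-gravity body force at time(s) ``t``.

    In the frame of the orbiting well the shaker motion appears as a rotating
    horizontal acceleration of constant magnitude ``A * omega**2`` (with the
    orbital radius ``A`` in metres) superposed on gravity:

        [A w^2 cos(w t),  A w^2 sin(w t),  -9.81]   (m/s^2)

    Parameters
    ----------
    t : float or array_like
        Time(s) in seconds, non-negative.
    geometry : WellGeometry

    Returns
    -------
    ndarray
        Shape ``(3,)`` for scalar ``t``, else ``(len(t), 3)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    amp = (geometry.orbital_radius * 1e-3) * geometry.angular_velocity**2
    phase = geometry.angular_velocity * t_arr
    out = np.stack(
        [
            amp * np.cos(phase),
            amp * np.sin(phase),
            np.full_like(t_arr, -GRAVITY),
        ],
        axis=-1,
    )
    return out


@dataclass(frozen=True)
class RegionAreas:
    """Areas of the two seeded regions and their relative difference.

    ``relative_difference_pct`` is ``|annulus - disc| / denominator * 100``;
    the denominator convention used is recorded in ``denominator``.
    """

    disc_area_mm2: float
    annulus_area_mm2: float
    relative_difference_pct: float
    denominator: str = "disc"


def region_areas(geometry: WellGeometry, denominator: str = "disc") -> RegionAreas:
    """Areas of the centre disc and edge annulus seeded regions.

    The experiment is designed so the two regions have nearly equal area
    (the relative difference is below 10% for the default radii).

    Parameters
    ----------
    geometry : WellGeometry
    denominator : {"disc", "annulus", "mean"}
        Which area normalizes the relative difference.
    """
    disc = math.pi * geometry.disc_radius**2
    annulus = math.pi * (geometry.well_radius**2 - geometry.annulus_inner_radius**2)
    denoms = {"disc": disc, "annulus": annulus, "mean": 0.5 * (disc + annulus)}
    if denominator not in denoms:
        raise ValueError(f"denominator must be one of {sorted(denoms)}")
    rel = abs(annulus - disc) / denoms[denominator] * 100.0
    return RegionAreas(disc, annulus, rel, denominator)


def classify_region(r, geometry: WellGeometry):
    """Label radial position(s) as ``centre``, ``gap`` or ``edge``.

    ``centre`` is the seeded disc (r <= disc_radius), ``edge`` the seeded
    annulus (r >= annulus_inner_radius), ``gap`` the unseeded ring between.

    Parameters
    ----------
    r : float or array_like
        Radial distance(s) from the well centre, mm, within [0, well_radius].
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > geometry.well_radius):
        raise ValueError("r must lie within [0, well_radius]")
    labels = np.where(
        r_arr <= geometry.disc_radius,
        "centre",
        np.where(r_arr >= geometry.annulus_inner_radius, "edge", "gap"),
    )
    if np.isscalar(r) or r_arr.ndim == 0:
        return str(labels)
    return labels
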