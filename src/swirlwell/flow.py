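"""Parametric surrogate for the swirling-well base shear field.

Full volume-of-fluid CFD of the orbited well is out of scope here; instead
this module synthesizes a WSS vector field with the flow structure that CFD
and experiment report for the swirling well:

* at the well centre the WSS vector has constant magnitude and rotates at the
  orbital rate (one full turn per cycle) — perfectly multidirectional,
  low-magnitude flow (LMMF);
* toward the wall the radial (outward) component is progressively suppressed,
  leaving a nearly circumferential, uniaxial vector whose magnitude
  fluctuates within a stated amplitude during each orbit — high-magnitude
  uniaxial flow (HMUF);
* the cycle-mean magnitude rises monotonically from a centre value to an
  edge value, and the whole pattern advances in phase with the orbit.

The local waveform, in the (radial, circumferential) basis at a point with
suppression ``s(r)`` and phase ``psi = omega*t - theta + psi0``, is

    w_r     = (1 - s) cos(psi)
    w_theta = (1 - s) sin(psi) + s (1 + a sin(psi))

which is the unit rotating vector at s=0 and a non-reversing fluctuating
circumferential vector at s=1.  Each point's waveform is rescaled so that its
cycle-mean magnitude equals the target magnitude profile M(r), a smoothstep
between centre and edge magnitudes; TAWSS therefore equals M(r) by
construction and OSI falls from 0.5 at the centre toward the edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import WellGeometry
from .series import WSSVectorSeries

__all__ = ["SurrogateFlowSpec", "synthesize_wss_field", "smoothstep", "default_point_grid"]


def smoothstep(x) -> np.ndarray:
    """Cubic smoothstep ``3x^2 - 2x^3`` clamped to [0, 1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class SurrogateFlowSpec:
    """Parameters of the surrogate base-shear field.

    Parameters
    ----------
    centre_magnitude : float
        Cycle-mean WSS magnitude at the well centre, Pa (default 0.3, the
        low-magnitude multidirectional regime).
    edge_magnitude : float
        Cycle-mean WSS magnitude at the wall, Pa (default 0.6, the
        high-magnitude uniaxial regime).
    radial_suppression : callable or None
        Profile ``s(x)`` of the radial-component suppression versus
        normalized radius ``x = r / well_radius``, with values in [0, 1]
        (0: free rotation, 1: fully circumferential).  ``None`` selects the
        default smoothstep from 0 at the centre to 1 at the wall.
    magnitude_fluctuation_amplitude : float
        Relative amplitude ``a`` of the circumferential magnitude
        fluctuation at the wall (dimensionless; < 1 keeps the edge vector
        non-reversing).
    samples_per_cycle : int
        Time samples per orbital cycle (>= 8).
    phase0 : float
        Phase offset of the orbit, rad.
    """

    centre_magnitude: float = 0.3
    edge_magnitude: float = 0.6
    radial_suppression: Callable[[np.ndarray], np.ndarray] | None = None
    magnitude_fluctuation_amplitude: float = 0.5
    samples_per_cycle: int = 64
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.centre_magnitude < 0 or self.edge_magnitude < 0:
            raise ValueError("magnitudes must be non-negative")
        if self.magnitude_fluctuation_amplitude < 0:
            raise ValueError("magnitude_fluctuation_amplitude must be >= 0")
        if self.samples_per_cycle < 8:
            raise ValueError("samples_per_cycle must be >= 8")

    def suppression(self, x) -> np.ndarray:
        prof = self.radial_suppression or smoothstep
        s = np.asarray(prof(np.asarray(x, dtype=float)), dtype=float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("radial_suppression values must lie in [0, 1]")
        return np.clip(s, 0.0, 1.0)

    def magnitude(self, x) -> np.ndarray:
        """Target cycle-mean magnitude at normalized radius ``x``."""
        return self.centre_magnitude + (
            self.edge_magnitude - self.centre_magnitude
        ) * smoothstep(x)


def default_point_grid(geometry: WellGeometry, n_r: int = 30, n_theta: int = 16):
    """Polar sampling grid on the base: ring radii x uniform angles.

    The innermost ring sits at r=0 (a single point) so the perfectly
    rotating centre is always represented.
    """
    radii = np.linspace(0.0, geometry.well_radius, n_r)
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    pts = [(0.0, 0.0)]
    for r in radii[1:]:
        pts.extend((r, th) for th in thetas)
    return np.array(pts)


def synthesize_wss_field(
    geometry: WellGeometry,
    spec: SurrogateFlowSpec,
    points: np.ndarray | None = None,
    n_r: int = 30,
    n_theta: int = 16,
    n_cycles: int = 1,
) -> WSSVectorSeries:
    """Generate a surrogate WSS vector series on the well base.

    Parameters
    ----------
    geometry : WellGeometry
    spec : SurrogateFlowSpec
    points : ndarray (n, 2), optional
        Polar points (r_mm, theta_rad); defaults to a ring grid.
    n_cycles : int
        Number of orbital cycles to sample (the field is periodic; one
        cycle suffices for the metrics).

    Returns
    -------
    WSSVectorSeries
        Half-open sampling of ``n_cycles`` cycles at
        ``spec.samples_per_cycle`` samples per cycle; ``tau_z = 0``.
    """
    if points is None:
        points = default_point_grid(geometry, n_r=n_r, n_theta=n_theta)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    omega = geometry.angular_velocity
    if omega <= 0:
        raise ValueError("surrogate flow requires a non-zero orbital rate")
    period = geometry.period
    n_t = spec.samples_per_cycle * n_cycles
    times = np.arange(n_t) * (period / spec.samples_per_cycle)

    r = points[:, 0]
    theta = points[:, 1]
    x = r / geometry.well_radius
    s = spec.suppression(x)[:, None]  # (n, 1)
    mag = spec.magnitude(x)[:, None]
    a = spec.magnitude_fluctuation_amplitude

    psi = omega * times[None, :] - theta[:, None] + spec.phase0  # (n, t)
    w_r = (1.0 - s) * np.cos(psi)
    w_t = (1.0 - s) * np.sin(psi) + s * (1.0 + a * np.sin(psi))

    # normalize each point's waveform so its cycle-mean magnitude is M(r);
    # the mean is taken with the same periodic trapezoid the metrics use
    w_mag = np.hypot(w_r, w_t)
    one_cycle = np.concatenate(
        [w_mag[:, : spec.samples_per_cycle], w_mag[:, :1]], axis=1
    )
    t_closed = np.arange(spec.samples_per_cycle + 1) * (period / spec.samples_per_cycle)
    mean_mag = np.trapezoid(one_cycle, t_closed, axis=1)[:, None] / period
    mean_mag[mean_mag == 0] = 1.0
    scale = mag / mean_mag

    tau_r = scale * w_r
    tau_t = scale * w_t
    cos_t, sin_t = np.cos(theta)[:, None], np.sin(theta)[:, None]
    tau_x = tau_r * cos_t - tau_t * sin_t
    tau_y = tau_r * sin_t + tau_t * cos_t
    vectors = np.stack([tau_x, tau_y, np.zeros_like(tau_x)], axis=2)

    return WSSVectorSeries(
        points=points,
        times=times,
        vectors=vectors,
        period_s=period,
        well_radius_mm=geometry.well_radius,
    )
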