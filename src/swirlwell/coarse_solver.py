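"""Coarse solver for the orbited-well base shear (scaled down).

Full volume-of-fluid CFD is out of scope; this module solves the smallest
model of the swirling well that produces a non-trivial base shear.  In the
co-moving frame the orbit is a rotating horizontal body force of magnitude
``A*omega**2``.  With a perfectly rigid flat lid that force is balanced
exactly by a pressure gradient and *no flow at all* results — the swirling
flow exists because the free surface responds.  The coarse model therefore
keeps the leading free-surface physics and nothing else:

* depth-averaged (shallow-water) momentum and mass equations, linearized
  about the resting 2 mm layer, on a staggered Cartesian grid masked to the
  circular well, with no-penetration side walls;
* the rotating body force of the orbit as the only forcing (gravity enters
  through the surface-elevation term ``-g grad(eta)``);
* an oscillatory Stokes-boundary-layer closure for the base: wall stress
  ``tau = rho*sqrt(nu*omega)*U`` aligned with the depth-averaged velocity,
  and the matching linear bottom friction ``sqrt(nu*omega)/h`` in the
  momentum equation.

The first azimuthal sloshing mode of a 2 mm layer in a 17.4 mm well has a
natural frequency close to the 150 rpm forcing, so the model captures the
near-resonant swirl response that makes orbital shakers effective.  What it
cannot capture — wave steepening, vertical structure beyond the boundary
layer closure — is exactly why the surrogate field, not this solver, carries
the quantitative flow structure.

Convergence of a run is monitored through the maximum base WSS per cycle
(declared converged when its relative change between successive cycles
drops below 1%), and the explicit scheme rejects time steps violating the
gravity-wave CFL limit with a suggestion for a stable step count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GRAVITY, WellGeometry, body_force
from .series import WSSVectorSeries

__all__ = [
    "CoarseGridSpec",
    "CoarseFlowResult",
    "solve_coarse_flow",
    "stable_samples_per_cycle",
]


@dataclass(frozen=True)
class CoarseGridSpec:
    """Resolution of the coarse solver: ``nx`` cells across the well
    diameter and ``samples_per_cycle`` time steps per orbital cycle."""

    nx: int = 48
    samples_per_cycle: int = 128

    def __post_init__(self) -> None:
        if self.nx < 8:
            raise ValueError("grid too coarse: need nx >= 8")
        if self.samples_per_cycle < 8:
            raise ValueError("samples_per_cycle must be >= 8")


@dataclass
class CoarseFlowResult:
    """Base WSS over the final cycle plus the convergence trace."""

    series: WSSVectorSeries
    max_wss_per_cycle: np.ndarray  # Pa, one entry per simulated cycle
    converged: bool
    convergence_tol: float

    @property
    def relative_changes(self) -> np.ndarray:
        m = self.max_wss_per_cycle
        prev = np.maximum(m[:-1], 1e-300)
        return np.abs(np.diff(m)) / prev


def _wave_dt_max(geometry: WellGeometry, grid: CoarseGridSpec) -> float:
    dx = 2 * geometry.well_radius * 1e-3 / grid.nx
    c = np.sqrt(GRAVITY * geometry.fluid_height * 1e-3)
    return 0.5 * dx / c


def stable_samples_per_cycle(geometry: WellGeometry, grid: CoarseGridSpec) -> int:
    """Smallest samples-per-cycle satisfying the gravity-wave CFL limit."""
    period = geometry.period if geometry.angular_velocity > 0 else 0.4
    return int(np.ceil(period / _wave_dt_max(geometry, grid)))


def solve_coarse_flow(
    geometry: WellGeometry,
    grid: CoarseGridSpec | None = None,
    n_cycles: int = 12,
    convergence_tol: float = 0.01,
) -> CoarseFlowResult:
    """Time-step the depth-averaged swirl model and return the base WSS.

    Parameters
    ----------
    geometry : WellGeometry
    grid : CoarseGridSpec
        Coarse resolution; the explicit step must satisfy the gravity-wave
        CFL limit or a ``ValueError`` naming the stable samples-per-cycle
        is raised.
    n_cycles : int
        Simulated orbital cycles (>= 2).  The first cycles are the
        spin-up transient; the final cycle is returned.  The default
        allows the near-resonant response to settle.
    convergence_tol : float
        Relative change in cycle-max base WSS below which the run is
        declared converged (default 1%).

    Returns
    -------
    CoarseFlowResult
        Base WSS sampled at every time step of the final cycle on the
        in-well cell centres, plus the per-cycle max-WSS trace.
    """
    if grid is None:
        grid = CoarseGridSpec()
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 (first cycle is transient)")
    forced = geometry.angular_velocity > 0
    period = geometry.period if forced else 0.4
    omega_clock = 2 * np.pi / period
    dt = period / grid.samples_per_cycle
    dt_max = _wave_dt_max(geometry, grid)
    if dt > dt_max:
        raise ValueError(
            f"time step {dt:.3e} s violates the gravity-wave CFL limit "
            f"{dt_max:.3e} s; use samples_per_cycle >= "
            f"{stable_samples_per_cycle(geometry, grid)}"
        )

    radius = geometry.well_radius * 1e-3
    depth = geometry.fluid_height * 1e-3
    nx = grid.nx
    dx = 2 * radius / nx
    nu = geometry.kinematic_viscosity
    rho = geometry.density
    # Stokes-layer closure at the forcing frequency
    stress_coef = rho * np.sqrt(nu * omega_clock)  # tau = coef * |U|
    r_f = np.sqrt(nu * omega_clock) / depth  # matching bottom friction, 1/s

    xc = (np.arange(nx) + 0.5) * dx - radius
    x2, y2 = np.meshgrid(xc, xc, indexing="ij")
    mask = x2**2 + y2**2 < radius**2
    a_u = np.zeros((nx + 1, nx), dtype=bool)
    a_u[1:nx] = mask[:-1] & mask[1:]
    a_v = np.zeros((nx, nx + 1), dtype=bool)
    a_v[:, 1:nx] = mask[:, :-1] & mask[:, 1:]

    u = np.zeros(a_u.shape)  # depth-averaged velocities on faces, m/s
    v = np.zeros(a_v.shape)
    eta = np.zeros(mask.shape)  # surface elevation, m

    max_per_cycle: list[float] = []
    base_frames = []
    times_last = []
    damp = 1.0 / (1.0 + dt * r_f)  # semi-implicit friction

    for step in range(n_cycles * grid.samples_per_cycle):
        t = step * dt
        fx, fy = (body_force(t, geometry)[:2] if forced else (0.0, 0.0))
        grad_x = (eta[1:, :] - eta[:-1, :]) / dx
        grad_y = (eta[:, 1:] - eta[:, :-1]) / dx
        u[1:nx] = np.where(
            a_u[1:nx], (u[1:nx] + dt * (-GRAVITY * grad_x + fx)) * damp, 0.0
        )
        v[:, 1:nx] = np.where(
            a_v[:, 1:nx], (v[:, 1:nx] + dt * (-GRAVITY * grad_y + fy)) * damp, 0.0
        )
        div = (u[1:] - u[:-1]) / dx + (v[:, 1:] - v[:, :-1]) / dx
        eta = np.where(mask, eta - dt * depth * div, 0.0)

        u_cc = 0.5 * (u[1:, :] + u[:-1, :])
        v_cc = 0.5 * (v[:, 1:] + v[:, :-1])
        tau_x = stress_coef * u_cc
        tau_y = stress_coef * v_cc
        tau_mag = np.hypot(tau_x, tau_y)[mask]
        if step % grid.samples_per_cycle == 0:
            max_per_cycle.append(0.0)
        max_per_cycle[-1] = max(max_per_cycle[-1], float(tau_mag.max(initial=0.0)))
        if step >= (n_cycles - 1) * grid.samples_per_cycle:
            base_frames.append(
                np.stack([tau_x[mask], tau_y[mask], np.zeros(int(mask.sum()))], axis=-1)
            )
            times_last.append(t)

    xs = x2[mask] * 1e3
    ys = y2[mask] * 1e3
    points = np.column_stack([np.hypot(xs, ys), np.arctan2(ys, xs)])
    series = WSSVectorSeries(
        points=points,
        times=np.asarray(times_last),
        vectors=np.stack(base_frames, axis=1),
        period_s=period,
        well_radius_mm=geometry.well_radius,
    )
    trace = np.asarray(max_per_cycle)
    if len(trace) >= 2 and trace[-2] > 0:
        converged = abs(trace[-1] - trace[-2]) / trace[-2] < convergence_tol
    else:
        converged = bool(trace[-1] == 0.0)
    return CoarseFlowResult(series, trace, converged, convergence_tol)
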