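"""Multidirectional wall-shear-stress metrics: TAWSS, OSI and transWSS.

Given instantaneous WSS vectors tau(t) over one forcing cycle of period T,
the three standard metrics are

    TAWSS    = (1/T) * integral |tau| dt
    OSI      = 1/2 * (1 - |integral tau dt| / integral |tau| dt)
    transWSS = (1/T) * integral | tau . (n x tau_mean/|tau_mean|) | dt

with |tau| = sqrt(tau_x^2 + tau_y^2 + tau_z^2) and n the unit surface normal
of the base.  TAWSS is the mean magnitude; OSI (0 to 0.5) measures how much
the instantaneous vectors deviate from their temporal mean direction (0 for
steady unidirectional shear, 0.5 for fully reversing or rotating shear);
transWSS is the mean magnitude of the component perpendicular, in the wall
plane, to the mean vector.

All integrals are discretized with the trapezoidal rule over exactly the
final full period of the series, closed periodically.  The wall-normal
component tau_z is included in magnitudes as the equations are written, even
though it is expected to be ~0 on the base.

Degenerate mean: the transWSS reference direction divides by |tau_mean|.
When |tau_mean| < 1e-6 * TAWSS * T the reference direction is replaced by the
principal eigenvector of the in-plane second-moment matrix of the vectors;
if that matrix is itself isotropic (perfectly rotating shear) an arbitrary
fixed in-plane axis is used — the result is then axis-independent — and the
point is flagged ``degenerate_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import WSSVectorSeries

__all__ = [
    "ShearMetricsField",
    "compute_tawss",
    "compute_osi",
    "compute_transwss",
    "compute_metrics",
    "radial_metric_profile",
]

#: |tau_mean| below this fraction of TAWSS counts as a degenerate mean
DEGENERATE_MEAN_RTOL = 1e-6
#: eigenvalue asymmetry below this counts as an isotropic second moment
ISOTROPY_RTOL = 1e-9

_BASE_NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass
class ShearMetricsField:
    """Per-point shear metrics with the quantities they derive from.

    Attributes
    ----------
    points : ndarray (n, 2)
        Polar positions (r_mm, theta_rad) copied from the input series.
    tawss, osi, transwss : ndarray (n,)
        The three metrics (Pa, dimensionless, Pa).
    mean_vector : ndarray (n, 3)
        Cycle-average WSS vector, Pa.
    reference_direction : ndarray (n, 3)
        In-plane unit vector the transWSS projection used (``n x m_hat``).
    degenerate_mean : ndarray (n,) of bool
        True where |mean| fell below tolerance and the fallback reference
        direction rule applied.
    """

    points: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    transwss: np.ndarray
    mean_vector: np.ndarray
    reference_direction: np.ndarray
    degenerate_mean: np.ndarray
    well_radius_mm: float | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        if np.any(self.tawss < -eps):
            raise ValueError("tawss must be non-negative")
        if np.any(self.osi < -eps) or np.any(self.osi > 0.5 + eps):
            raise ValueError("osi must lie in [0, 0.5]")
        if np.any(self.transwss < -eps) or np.any(
            self.transwss > self.tawss * (1 + 1e-9) + eps
        ):
            raise ValueError("transwss must lie in [0, tawss]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_mm": self.points[:, 0],
                "theta_rad": self.points[:, 1],
                "tawss_Pa": self.tawss,
                "osi": self.osi,
                "transwss_Pa": self.transwss,
                "degenerate_mean": self.degenerate_mean,
            }
        )


def _cycle_integrals(series: WSSVectorSeries):
    """Trapezoidal ``(T, int tau dt, int |tau| dt)`` over the final period."""
    t, v = series.last_period()
    mag = np.linalg.norm(v, axis=2)  # (n, m)
    int_vec = np.trapezoid(v, t, axis=1)  # (n, 3)
    int_mag = np.trapezoid(mag, t, axis=1)  # (n,)
    period = t[-1] - t[0]
    return period, int_vec, int_mag


def compute_tawss(series: WSSVectorSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per point, Pa."""
    period, _, int_mag = _cycle_integrals(series)
    return int_mag / period


def compute_osi(series: WSSVectorSeries) -> np.ndarray:
    """Oscillatory shear index per point, in [0, 0.5].

    An identically zero series has no defined OSI; such points are returned
    as 0 (flagged in :func:`compute_metrics`).
    """
    _, int_vec, int_mag = _cycle_integrals(series)
    out = np.zeros(series.n_points)
    ok = int_mag > 0
    out[ok] = 0.5 * (1.0 - np.linalg.norm(int_vec[ok], axis=1) / int_mag[ok])
    # clamp tiny quadrature overshoot
    return np.clip(out, 0.0, 0.5)


def _reference_directions(series, normal, int_vec, int_mag, period):
    """Unit transWSS projection axes ``n x m_hat`` plus degeneracy flags."""
    n_pts = series.n_points
    refs = np.empty((n_pts, 3))
    degenerate = np.zeros(n_pts, dtype=bool)
    mean_vec = int_vec / period
    tawss = int_mag / period
    _, v = series.last_period()
    for i in range(n_pts):
        m = mean_vec[i]
        m_norm = np.linalg.norm(m)
        if tawss[i] == 0.0:
            degenerate[i] = True
            refs[i] = np.cross(normal, [1.0, 0.0, 0.0])
            continue
        if m_norm >= DEGENERATE_MEAN_RTOL * tawss[i]:
            refs[i] = np.cross(normal, m / m_norm)
            continue
        degenerate[i] = True
        # principal axis of the in-plane second moment of the vectors
        vi = v[i]
        in_plane = vi - np.outer(vi @ normal, normal)
        second = in_plane.T @ in_plane
        evals, evecs = np.linalg.eigh(second)
        if evals[-1] <= 0 or (evals[-1] - evals[-2]) <= ISOTROPY_RTOL * evals[-1]:
            axis = np.array([1.0, 0.0, 0.0])  # isotropic: arbitrary fixed axis
            if abs(np.dot(axis, normal)) > 0.9:
                axis = np.array([0.0, 1.0, 0.0])
        else:
            axis = evecs[:, -1]
        refs[i] = np.cross(normal, axis / np.linalg.norm(axis))
    norms = np.linalg.norm(refs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return refs / norms, degenerate


def compute_transwss(series: WSSVectorSeries, normal=_BASE_NORMAL) -> np.ndarray:
    """Transverse WSS per point, Pa, in [0, TAWSS]."""
    return compute_metrics(series, normal=normal).transwss


def compute_metrics(series: WSSVectorSeries, normal=_BASE_NORMAL) -> ShearMetricsField:
    """Compute TAWSS, OSI and transWSS for every point of a series.

    Parameters
    ----------
    series : WSSVectorSeries
        Must span at least one full period; the final full period is used.
    normal : array_like, shape (3,)
        Unit surface normal of the base (default +z, the outward normal of
        the monolayer).
    """
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
        raise ValueError("normal must be a unit vector")
    period, int_vec, int_mag = _cycle_integrals(series)
    tawss = int_mag / period
    osi = np.zeros(series.n_points)
    ok = int_mag > 0
    osi[ok] = 0.5 * (1.0 - np.linalg.norm(int_vec[ok], axis=1) / int_mag[ok])
    osi = np.clip(osi, 0.0, 0.5)

    refs, degenerate = _reference_directions(series, normal, int_vec, int_mag, period)
    degenerate |= ~ok  # identically zero points

    t, v = series.last_period()
    proj = np.abs(np.einsum("ntk,nk->nt", v, refs))
    transwss = np.trapezoid(proj, t, axis=1) / period
    transwss = np.minimum(transwss, tawss)  # guard quadrature round-off

    return ShearMetricsField(
        points=series.points.copy(),
        tawss=tawss,
        osi=osi,
        transwss=transwss,
        mean_vector=int_vec / period,
        reference_direction=refs,
        degenerate_mean=degenerate,
        well_radius_mm=series.well_radius_mm,
    )


def radial_metric_profile(
    field: ShearMetricsField, bin_width_mm: float = 1.0,
    well_radius_mm: float | None = None,
) -> pd.DataFrame:
    """Bin a metrics field into radial intervals and average each metric.

    Bins are half-open ``[k*w, (k+1)*w)`` mm from 0 to the well radius, the
    last bin closed at the wall.  Empty bins are reported with NaN metrics
    (missing, not zero).

    Returns
    -------
    DataFrame
        Columns: bin_lo_mm, bin_hi_mm, r_mid_mm, n_points, tawss_Pa, osi,
        transwss_Pa.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    radius = well_radius_mm or field.well_radius_mm
    if radius is None:
        radius = float(np.max(field.points[:, 0]))
    n_bins = max(1, int(np.ceil(radius / bin_width_mm - 1e-9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width_mm, radius)
    r = field.points[:, 0]
    idx = np.minimum((r / bin_width_mm).astype(int), n_bins - 1)

    rows = []
    for k in range(n_bins):
        sel = idx == k
        n = int(np.count_nonzero(sel))
        rows.append(
            {
                "bin_lo_mm": edges[k],
                "bin_hi_mm": edges[k + 1],
                "r_mid_mm": 0.5 * (edges[k] + edges[k + 1]),
                "n_points": n,
                "tawss_Pa": float(np.mean(field.tawss[sel])) if n else np.nan,
                "osi": float(np.mean(field.osi[sel])) if n else np.nan,
                "transwss_Pa": float(np.mean(field.transwss[sel])) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
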