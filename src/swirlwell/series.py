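"""Time-resolved wall-shear-stress vector series on the well base.

The central container is :class:`WSSVectorSeries`: instantaneous WSS vectors
(Pa) sampled at a set of polar points on the base of the well and at a set of
strictly increasing times spanning at least one full orbital period.  Series
can be generated internally (surrogate flow, coarse solver, synthetic test
waveforms) or imported from CFD exports (long-format CSV, or a sequence of
legacy-ASCII VTK polydata files, one per time step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["WSSVectorSeries", "read_wss_csv", "read_vtk_polydata", "read_vtk_series"]

_CSV_COLUMNS = ["r_mm", "theta_rad", "t_s", "tau_x_Pa", "tau_y_Pa", "tau_z_Pa"]


@dataclass
class WSSVectorSeries:
    """Instantaneous WSS vectors sampled in time at points on the well base.

    Attributes
    ----------
    points : ndarray, shape (n_points, 2)
        Polar positions ``(r_mm, theta_rad)`` on the base; theta is measured
        counter-clockwise from +x.
    times : ndarray, shape (n_times,)
        Sample times in seconds, strictly increasing.
    vectors : ndarray, shape (n_points, n_times, 3)
        WSS vector components ``(tau_x, tau_y, tau_z)`` in Pa.
    period_s : float
        Period of the forcing cycle, seconds.  The series must span at least
        one full period.
    well_radius_mm : float or None
        Radius of the well the points live on; used for validation and
        radial binning when available.
    """

    points: np.ndarray
    times: np.ndarray
    vectors: np.ndarray
    period_s: float
    well_radius_mm: float | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.points.shape[1] != 2:
            raise ValueError("points must have shape (n_points, 2)")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be a 1-D array with at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        expected = (self.points.shape[0], len(self.times), 3)
        if self.vectors.shape != expected:
            raise ValueError(
                f"vectors must have shape {expected}, got {self.vectors.shape}"
            )
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")
        if self.well_radius_mm is not None and np.any(
            self.points[:, 0] > self.well_radius_mm * (1 + 1e-9)
        ):
            raise ValueError("all point radii must be <= well_radius_mm")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def radii_mm(self) -> np.ndarray:
        return self.points[:, 0]

    def spans_full_period(self, rtol: float = 1e-6) -> bool:
        """Whether the sampled times cover at least one full period.

        A half-open sampling ``t0 .. t0 + T - dt`` counts as a full period
        (the missing endpoint is supplied by periodic closure).
        """
        span = self.times[-1] - self.times[0]
        dt = np.max(np.diff(self.times))
        return span >= self.period_s - dt - rtol * self.period_s

    def last_period(self, rtol: float = 1e-6):
        """Times and vectors of the final full period, closed periodically.

        Returns ``(t, v)`` where ``t`` is shape ``(m,)`` covering exactly one
        period (``t[-1] - t[0] == period_s``) and ``v`` is ``(n_points, m, 3)``.
        If the raw samples stop one step short of the period (half-open
        sampling), the first sample of the window is re-used as the closing
        sample under the periodicity assumption.
        """
        if not self.spans_full_period(rtol):
            raise ValueError(
                "series must span at least one full period "
                f"(span {self.times[-1] - self.times[0]:.6g} s < period {self.period_s:.6g} s)"
            )
        t_end = self.times[-1]
        t0 = t_end - self.period_s
        sel = self.times >= t0 - rtol * self.period_s
        t = self.times[sel]
        v = self.vectors[:, sel, :]
        span = t[-1] - t[0]
        if span < self.period_s * (1 - rtol):
            # half-open sampling: close the cycle with the first sample
            t = np.append(t, t[0] + self.period_s)
            v = np.concatenate([v, v[:, :1, :]], axis=1)
        return t, v

    def rotated(self, angle_rad: float) -> "WSSVectorSeries":
        """Series with every vector rigidly rotated about the surface normal."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return WSSVectorSeries(
            points=self.points.copy(),
            times=self.times.copy(),
            vectors=self.vectors @ rot.T,
            period_s=self.period_s,
            well_radius_mm=self.well_radius_mm,
        )

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns r_mm, theta_rad, t_s, tau_{x,y,z}_Pa."""
        n_p, n_t = self.n_points, len(self.times)
        rr = np.repeat(self.points[:, 0], n_t)
        th = np.repeat(self.points[:, 1], n_t)
        tt = np.tile(self.times, n_p)
        flat = self.vectors.reshape(n_p * n_t, 3)
        return pd.DataFrame(
            {
                "r_mm": rr,
                "theta_rad": th,
                "t_s": tt,
                "tau_x_Pa": flat[:, 0],
                "tau_y_Pa": flat[:, 1],
                "tau_z_Pa": flat[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        """Write the series as long-format CSV with a metadata comment header."""
        path = Path(path)
        header = (
            f"# period_s={self.period_s!r}\n"
            f"# well_radius_mm={self.well_radius_mm!r}\n"
            "# convention=right-handed, origin at well centre, theta CCW from +x,"
            " orbit phase advances CCW\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False)


def read_wss_csv(path) -> WSSVectorSeries:
    """Read a long-format WSS CSV written by :meth:`WSSVectorSeries.to_csv`.

    The file must contain a complete (points x times) grid.  ``period_s`` is
    taken from the ``# period_s=...`` comment header.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"WSS CSV missing columns: {missing}")
    if "period_s" not in meta:
        raise ValueError("WSS CSV lacks the '# period_s=' metadata header")
    period = float(meta["period_s"])
    radius = meta.get("well_radius_mm")
    radius_val = None if radius in (None, "None") else float(radius)

    times = np.unique(df["t_s"].to_numpy())
    pts = df[["r_mm", "theta_rad"]].drop_duplicates().to_numpy()
    n_p, n_t = len(pts), len(times)
    if len(df) != n_p * n_t:
        raise ValueError("WSS CSV does not contain a complete points x times grid")
    order = df.sort_values(["r_mm", "theta_rad", "t_s"], kind="mergesort")
    pts_sorted = order[["r_mm", "theta_rad"]].drop_duplicates().to_numpy()
    vectors = (
        order[["tau_x_Pa", "tau_y_Pa", "tau_z_Pa"]].to_numpy().reshape(n_p, n_t, 3)
    )
    return WSSVectorSeries(pts_sorted, times, vectors, period, radius_val)


# --------------------------------------------------------------------- VTK

def read_vtk_polydata(path):
    """Read points and a vector field from a legacy-ASCII VTK polydata file.

    Minimal reader for CFD surface exports: parses the ``POINTS`` block and
    the first ``VECTORS`` array in ``POINT_DATA``.  Returns ``(xyz, vec)``
    as float arrays of shape (n, 3).  Coordinates are returned as stored
    (callers decide the length unit).
    """
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise ValueError(f"{path}: not a legacy VTK file")
    if lines[2].strip().upper() != "ASCII":
        raise ValueError(f"{path}: only ASCII legacy VTK is supported")

    i = 0
    n_points = None
    xyz = None
    vec = None
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0].upper() == "POINTS":
            n_points = int(parts[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            xyz = np.array(vals, dtype=float).reshape(n_points, 3)
            continue
        if parts and parts[0].upper() == "VECTORS":
            if n_points is None:
                raise ValueError(f"{path}: VECTORS before POINTS")
            vals = []
            i += 1
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            vec = np.array(vals, dtype=float).reshape(n_points, 3)
            continue
        i += 1
    if xyz is None:
        raise ValueError(f"{path}: no POINTS block found")
    if vec is None:
        raise ValueError(f"{path}: no VECTORS point-data block found")
    return xyz, vec


def read_vtk_series(
    paths: Sequence, times: Sequence[float], period_s: float,
    length_unit_mm: float = 1.0, well_radius_mm: float | None = None,
) -> WSSVectorSeries:
    """Assemble a :class:`WSSVectorSeries` from per-time-step VTK files.

    Parameters
    ----------
    paths, times
        One legacy-ASCII VTK polydata file per sample time (same point set
        and ordering in every file).
    period_s : float
        Forcing period of the imported cycle.
    length_unit_mm : float
        Multiplier converting the stored coordinates to mm (e.g. 1000 for
        metres).
    """
    if len(paths) != len(times):
        raise ValueError("paths and times must have equal length")
    if len(paths) < 2:
        raise ValueError("need at least two time steps")
    xyz0 = None
    vecs = []
    for p in paths:
        xyz, vec = read_vtk_polydata(p)
        if xyz0 is None:
            xyz0 = xyz
        elif xyz.shape != xyz0.shape or not np.allclose(xyz, xyz0):
            raise ValueError("all VTK files must share one point set")
        vecs.append(vec)
    x = xyz0[:, 0] * length_unit_mm
    y = xyz0[:, 1] * length_unit_mm
    points = np.column_stack([np.hypot(x, y), np.arctan2(y, x)])
    vectors = np.stack(vecs, axis=1)  # (n_points, n_times, 3)
    return WSSVectorSeries(points, np.asarray(times, float), vectors, period_s,
                           well_radius_mm)
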