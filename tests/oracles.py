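"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's own code paths: shear-metric
integrals are evaluated by midpoint Riemann sums of the *continuous*
waveform at 1e5 samples, and ellipse geometry is checked against dense
rasterization.
"""

from __future__ import annotations

import numpy as np

BASE_NORMAL = np.array([0.0, 0.0, 1.0])


def riemann_metrics(waveform, period: float, n: int = 100_000, axis=None) -> dict:
    """TAWSS/OSI/transWSS of a continuous waveform by midpoint Riemann sum.

    ``axis``: in-plane reference axis used when the mean vector vanishes
    (e.g. a rotating waveform, where the result is axis-independent).
    """
    t = (np.arange(n) + 0.5) * (period / n)
    v = np.asarray(waveform(t), dtype=float)
    mag = np.linalg.norm(v, axis=-1)
    tawss = float(np.mean(mag))
    mean_vec = v.mean(axis=0)
    int_mag = np.sum(mag)
    osi = 0.5 * (1.0 - np.linalg.norm(mean_vec) * n / int_mag) if int_mag > 0 else 0.0
    m_norm = np.linalg.norm(mean_vec)
    if m_norm > 1e-6 * max(tawss, 1e-300):
        ref = np.cross(BASE_NORMAL, mean_vec / m_norm)
    else:
        if axis is None:
            axis = np.array([1.0, 0.0, 0.0])
        axis = np.asarray(axis, dtype=float)
        ref = np.cross(BASE_NORMAL, axis / np.linalg.norm(axis))
    ref = ref / np.linalg.norm(ref)
    transwss = float(np.mean(np.abs(v @ ref)))
    return {"tawss": tawss, "osi": float(osi), "transwss": transwss}


def rasterize_ellipse(semi_major_px: float, semi_minor_px: float,
                      angle_deg: float, pad: int = 4) -> np.ndarray:
    """Boolean pixel mask of a filled ellipse (physical-frame angle)."""
    half = int(np.ceil(semi_major_px)) + pad
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    ang = np.deg2rad(angle_deg)
    c, s = np.cos(ang), np.sin(ang)
    dx = xx.astype(float)
    dy = -yy.astype(float)  # image rows increase downward
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0
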