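"""Monocyte adhesion quantification: spot counting and THP-1:HUVEC ratios.

Adhered calcein-labelled monocytes appear as compact bright spots in a second
fluorescence channel.  They are counted with the same intensity-and-area
thresholding operator as the nuclei (with a smaller default area window), and
the count in each region is normalised by the endothelial nucleus count of
the same region, giving the THP-1:HUVEC ratio.  Field counts are pooled per
well before taking the ratio; summaries report mean +/- SEM across wells per
(region x treatment x segmentation) condition.  Hypothesis testing is left
to downstream statistics packages; this module emits tidy per-well tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import ImageFrame
from .morphometry import segment_nuclei

__all__ = ["AdhesionResult", "count_spots", "adhesion_ratio", "region_summary",
           "DEFAULT_SPOT_AREA_UM2"]

#: default spot area window, um^2 (calcein-stained monocytes are smaller
#: and rounder than endothelial nuclei)
DEFAULT_SPOT_AREA_UM2 = (10.0, 200.0)


@dataclass(frozen=True)
class AdhesionResult:
    """Adhesion readout for one region of one well."""

    region: str  # "centre" | "edge"
    thp1_count: int
    huvec_count: int
    ratio: float  # NaN when huvec_count == 0
    thp1_density_per_mm2: float


def count_spots(
    frame: ImageFrame,
    threshold="otsu",
    area_range_um2: tuple[float, float] = DEFAULT_SPOT_AREA_UM2,
) -> int:
    """Count fluorescent spots by intensity and area thresholding.

    Reuses the nucleus segmentation operator (connected components above an
    intensity threshold, filtered by physical area) with the spot-sized
    area window.
    """
    det = segment_nuclei(
        frame, threshold=threshold, area_range_um2=area_range_um2,
        refine_halfmax=False,
    )
    return len(det)


def adhesion_ratio(thp1_count: int, huvec_count: int) -> float:
    """THP-1 count normalised by HUVEC count in the same region."""
    if thp1_count < 0 or huvec_count < 0:
        raise ValueError("counts must be non-negative")
    if huvec_count == 0:
        raise ValueError("adhesion ratio undefined for huvec_count = 0")
    return thp1_count / huvec_count


def region_summary(
    counts: pd.DataFrame,
    per_field: bool = False,
    field_area_mm2: float | None = None,
) -> pd.DataFrame:
    """Mean +/- SEM adhesion readouts per (region, condition, segmentation).

    Parameters
    ----------
    counts : DataFrame
        Tidy per-field table with columns ``well_id, condition, segmented,
        region, field, thp1_count, huvec_count``.
    per_field : bool
        If False (default) field counts are pooled per well and the ratio
        is taken on the pooled counts; if True the ratio is computed per
        field and then averaged within each well.
    field_area_mm2 : float, optional
        Imaged area of one field; enables the absolute THP-1 density
        column.

    Returns
    -------
    DataFrame
        One row per (condition, segmented, region): ``n_wells, ratio_mean,
        ratio_sem, thp1_density_mean, thp1_density_sem``.  SEM is NaN for
        a single well (reported missing, not zero).
    """
    required = {"well_id", "condition", "segmented", "region", "thp1_count", "huvec_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")

    def _well_stats(g: pd.DataFrame) -> pd.Series:
        thp1 = g["thp1_count"].to_numpy(dtype=float)
        huv = g["huvec_count"].to_numpy(dtype=float)
        if per_field:
            ok = huv > 0
            ratio = float(np.mean(thp1[ok] / huv[ok])) if ok.any() else np.nan
        else:
            ratio = thp1.sum() / huv.sum() if huv.sum() > 0 else np.nan
        dens = (
            thp1.sum() / (len(g) * field_area_mm2)
            if field_area_mm2 else np.nan
        )
        return pd.Series({"ratio": ratio, "thp1_density": dens})

    keys = ["condition", "segmented", "region"]
    per_well = (
        counts.groupby(keys + ["well_id"], sort=True)
        .apply(_well_stats, include_groups=False)
        .reset_index()
    )

    rows = []
    for key, g in per_well.groupby(keys, sort=True):
        ratios = g["ratio"].to_numpy(dtype=float)
        dens = g["thp1_density"].to_numpy(dtype=float)
        n = int(np.sum(np.isfinite(ratios)))
        row = dict(zip(keys, key))
        row["n_wells"] = n
        row["ratio_mean"] = float(np.nanmean(ratios)) if n else np.nan
        row["ratio_sem"] = (
            float(np.nanstd(ratios, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        )
        nd = int(np.sum(np.isfinite(dens)))
        row["thp1_density_mean"] = float(np.nanmean(dens)) if nd else np.nan
        row["thp1_density_sem"] = (
            float(np.nanstd(dens, ddof=1) / np.sqrt(nd)) if nd > 1 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
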