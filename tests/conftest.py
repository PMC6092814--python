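"""Shared fixtures: default geometry and the heavy synthetic datasets.

The multi-well datasets are session-scoped because generating and
segmenting ten full radial strips (and 240 adhesion fields) dominates the
suite's runtime; every test that needs them shares one realization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import swirlwell as sw

N_STRIP_WELLS = 10
STRIP_SEED_BASE = 1234
ADHESION_SEED_BASE = 5678
N_ADHESION_WELLS = 6
MATCH_TOL_PX = 3.0


@pytest.fixture(scope="session")
def geometry() -> sw.WellGeometry:
    return sw.WellGeometry()


def match_detections(truth: pd.DataFrame, detections: pd.DataFrame,
                     tol_px: float = MATCH_TOL_PX):
    """Pair ground-truth nuclei with detections by nearest centroid.

    Returns ``(n_matched, idx)`` where ``idx[i]`` is the detection matched
    to truth row ``i`` (valid where the distance is within ``tol_px``).
    """
    tr = truth[["x_px", "y_px"]].to_numpy()
    de = detections[["x_px", "y_px"]].to_numpy()
    d, idx = cKDTree(de).query(tr)
    return int(np.sum(d <= tol_px)), idx, d


@pytest.fixture(scope="session")
def strip_dataset():
    """Ten seed-fixed synthetic radial-strip wells, segmented end to end.

    Returns a list of dicts with the generator spec, ground truth,
    detections, per-well truth/detected radial profiles and metadata.
    """
    wells = []
    for i in range(N_STRIP_WELLS):
        spec = sw.SyntheticWellSpec(seed=STRIP_SEED_BASE + i)
        frame, truth, meta = sw.generate_radial_strip(spec)
        det = sw.segment_nuclei(frame)
        areas = sw.strip_bin_areas_mm2(meta)
        prof_det = sw.bin_by_radius(det, areas, 1.0, meta["well_radius_mm"])
        prof_truth = sw.bin_by_radius(truth, areas, 1.0, meta["well_radius_mm"])
        wells.append(
            {
                "spec": spec,
                "truth": truth,
                "detections": det,
                "profile": prof_det,
                "truth_profile": prof_truth,
                "meta": meta,
            }
        )
    return wells


@pytest.fixture(scope="session")
def adhesion_dataset():
    """Detected adhesion counts for the TNF-alpha segmentation contrast.

    Six wells per (segmented, full) arm, ten 512 px fields per region, all
    counts produced by running the segmentation/spot-counting pipeline on
    the generated images.  Returns ``(counts, spec)`` where ``counts`` is
    the tidy per-field table expected by ``region_summary``.
    """
    spec = sw.SyntheticWellSpec(seed=ADHESION_SEED_BASE)
    rows = []
    truth_rows = []
    seed = ADHESION_SEED_BASE
    for segmented in (False, True):
        for region in ("centre", "edge"):
            for well in range(N_ADHESION_WELLS):
                seed += 1
                fields, truth = sw.generate_adhesion_images(
                    spec, condition="tnf", segmented=segmented, region=region,
                    n_fields=10, seed=seed,
                )
                for k, (nuc, spot) in enumerate(fields):
                    huvec = len(sw.segment_nuclei(nuc))
                    thp1 = sw.count_spots(spot)
                    rows.append(
                        {
                            "well_id": f"{'seg' if segmented else 'full'}-{region}-{well}",
                            "condition": "tnf",
                            "segmented": segmented,
                            "region": region,
                            "field": k,
                            "thp1_count": thp1,
                            "huvec_count": huvec,
                        }
                    )
                truth_rows.append(truth)
    return pd.DataFrame(rows), spec, pd.concat(truth_rows, ignore_index=True)
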