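"""Quantify monocyte adhesion on synthetic two-channel fields.

Generates paired nuclei/spot channels for the centre and edge regions of
segmented and full wells under TNF-alpha, counts both channels with the
segmentation pipeline, and prints the THP-1:HUVEC ratio summary.
"""

import pandas as pd

import swirlwell as sw

spec = sw.SyntheticWellSpec(seed=0)
rows = []
seed = 100
for segmented in (False, True):
    for region in ("centre", "edge"):
        for well in range(3):
            seed += 1
            fields, _ = sw.generate_adhesion_images(
                spec, condition="tnf", segmented=segmented, region=region,
                n_fields=5, seed=seed,
            )
            for k, (nuclei, spots) in enumerate(fields):
                rows.append(
                    {
                        "well_id": f"{'seg' if segmented else 'full'}-{region}-{well}",
                        "condition": "tnf", "segmented": segmented,
                        "region": region, "field": k,
                        "huvec_count": len(sw.segment_nuclei(nuclei)),
                        "thp1_count": sw.count_spots(spots),
                    }
                )

summary = sw.region_summary(pd.DataFrame(rows))
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

for region in ("centre", "edge"):
    exp_full = sw.expected_adhesion_ratio(spec, "tnf", False, region)
    exp_seg = sw.expected_adhesion_ratio(spec, "tnf", True, region)
    print(f"expected {region}: full {exp_full:.3f}, segmented {exp_seg:.3f}")

print(
    "\nThe ratio of adhered THP-1 monocytes to HUVEC rises with growth"
    "\nsegmentation at the well centre only: confining cells to the centre"
    "\nremoves the anti-inflammatory conditioning from edge cells."
)
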