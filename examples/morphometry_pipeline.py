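"""Segment a synthetic nuclear image and summarize morphology by radius.

Generates a small synthetic well (scaled down for a quick demo), runs the
nucleus segmentation, and prints per-bin cell density, shape index and
modal orientation next to the generator's ground truth.
"""

import numpy as np

import swirlwell as sw

spec = sw.SyntheticWellSpec(seed=0)
frame, truth, meta = sw.generate_radial_strip(spec, strip_height_mm=0.4)
print(f"strip image {frame.pixels.shape[1]} x {frame.pixels.shape[0]} px, "
      f"{meta['pixel_size_um']} um/px, {len(truth)} ground-truth nuclei")

detections = sw.segment_nuclei(frame)
print(f"detected {len(detections)} nuclei")

areas = sw.strip_bin_areas_mm2(meta, bin_width_mm=2.0)
profile = sw.bin_by_radius(detections, areas, bin_width_mm=2.0,
                           well_radius_mm=meta["well_radius_mm"])

print(f"\n{'r (mm)':>7s} {'count':>6s} {'/mm^2':>7s} {'true/mm^2':>9s} "
      f"{'SI':>6s} {'true SI':>8s} {'mode (deg)':>10s}")
for _, row in profile.iterrows():
    r = row["r_mid_mm"]
    a_um, b_um = spec.semi_axes_um(r)
    si_true = sw.shape_index(np.pi * a_um * b_um, sw.ellipse_perimeter(a_um, b_um))
    print(
        f"{r:7.1f} {row['count']:6.0f} {row['density_per_mm2']:7.0f} "
        f"{spec.density(r):9.0f} {row['si_mean']:6.3f} {si_true:8.3f} "
        f"{row['orientation_mode_deg']:10.1f}"
    )

fit = sw.fit_orientation_profile(profile)
print(f"\norientation-vs-radius polynomial fit of degree {fit.degree}")
print(
    "\nDensity and nuclear elongation rise from centre to edge and nuclei"
    "\nalign circumferentially (mode near +/-90 deg) where shear is uniaxial;"
    "\nnear the centre the orientation mode is meaningless (no alignment)."
)
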