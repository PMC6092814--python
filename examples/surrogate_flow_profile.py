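"""Radial shear-metric profiles of the surrogate swirling-well field.

Synthesizes one orbital cycle of the surrogate base shear in a 6-well plate
well orbited at 150 rpm and prints TAWSS/OSI/transWSS in 1-mm radial bins,
with the seeded-region label of each bin.
"""

import swirlwell as sw

geometry = sw.WellGeometry()  # 17.4 mm well, 5 mm orbit, 150 rpm
spec = sw.SurrogateFlowSpec()  # 0.3 Pa centre -> 0.6 Pa edge

series = sw.synthesize_wss_field(geometry, spec, n_r=36, n_theta=12)
field = sw.compute_metrics(series)
profile = sw.radial_metric_profile(field, bin_width_mm=1.0)

print(f"{'r (mm)':>8s} {'region':>8s} {'TAWSS (Pa)':>11s} {'OSI':>7s} {'transWSS':>9s}")
for _, row in profile.dropna(subset=["tawss_Pa"]).iterrows():
    r = min(row["r_mid_mm"], geometry.well_radius)
    label = sw.classify_region(r, geometry)
    print(
        f"{row['r_mid_mm']:8.1f} {label:>8s} {row['tawss_Pa']:11.3f} "
        f"{row['osi']:7.3f} {row['transwss_Pa']:9.3f}"
    )

ra = sw.region_areas(geometry)
print(
    f"\nSeeded regions: centre disc {ra.disc_area_mm2:.0f} mm^2, edge annulus "
    f"{ra.annulus_area_mm2:.0f} mm^2 ({ra.relative_difference_pct:.1f}% apart).\n"
    "The centre experiences low-magnitude multidirectional shear (OSI ~ 0.5),\n"
    "the edge high-magnitude nearly uniaxial shear (OSI ~ 0)."
)
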