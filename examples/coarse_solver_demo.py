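"""Run the depth-averaged coarse swirl solver and show its convergence.

Time-steps the linearized shallow-water model of the orbited well and
prints the cycle-maximum base WSS trace (the convergence monitor) plus the
radially binned TAWSS of the final cycle.  The linear model captures the
near-resonant swirl but not the edge-concentrated shear of the full
free-surface CFD — see docs/methods.md.
"""

import swirlwell as sw

geometry = sw.WellGeometry()
grid = sw.CoarseGridSpec(nx=48, samples_per_cycle=192)
result = sw.solve_coarse_flow(geometry, grid, n_cycles=14)

print("cycle-max base WSS (Pa) per cycle:")
for k, m in enumerate(result.max_wss_per_cycle):
    print(f"  cycle {k:2d}: {m:7.4f}")
print(f"converged (<{result.convergence_tol:.0%} change): {result.converged}")

field = sw.compute_metrics(result.series)
profile = sw.radial_metric_profile(field, bin_width_mm=2.0)
print("\nfinal-cycle TAWSS vs radius:")
for _, row in profile.dropna(subset=["tawss_Pa"]).iterrows():
    print(f"  r = {row['r_mid_mm']:5.1f} mm: TAWSS {row['tawss_Pa']:.3f} Pa, "
          f"OSI {row['osi']:.3f}")
print(
    "\nOSI ~ 0.5 everywhere: the depth-averaged sloshing response rotates"
    "\nwith the orbit at every radius."
)
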