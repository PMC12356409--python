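"""Membrane FRAP: slow receptor diffusion vs a fast cytosolic reporter.

Simulates photobleaching on a closed cortical membrane patch and runs the
normalization pipeline.  A receptor-like species (D ~ 0.005 um^2/s)
recovers only a small fraction of its bleached deficit within 5 minutes,
while a cytosol-like species (D ~ 5 um^2/s) recovers almost fully.
"""

import embryograd as eg

for name, d_coeff in {"receptor-like": 0.005, "cytosolic reporter-like": 5.0}.items():
    scene, truth = eg.render_frap_series(
        d_coeff_um2_s=d_coeff, bleach_radius_um=5.0, bleach_depth=0.9,
        duration_s=300.0, interval_s=10.0, seed=5, domain_um=50.0,
    )
    center = tuple((s - 1) / 2.0 for s in scene.pixels.shape[-2:])
    trace = eg.extract_frap_trace(
        scene, eg.RoiBox(center, 4.0, "in bleach"),
        eg.RoiBox((10.0, 42.0), 6.0, "outside"), background_au=truth.offset_au,
    )
    curve = eg.normalize_frap(trace, mode="simple")
    rho = eg.recovery_at(curve, 300.0)
    print(f"{name:24s} D={d_coeff:<6} R(0+)={curve.values[1]:.2f} "
          f"R(300 s)={curve.at(300.0):.2f}  deficit recovery rho={100 * rho:.1f}%")

print("\nrho < 50% at 5 min is the signature of a membrane-confined, slowly"
      "\ndiffusing species; total intensity is conserved exactly post-bleach,"
      "\nso the well-mixed plateau is predictable from bookkeeping alone.")
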