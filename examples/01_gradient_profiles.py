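"""Receptor-activity gradients across nuclear cycles.

Renders noise-free synthetic embryos for NC11-NC14, runs the standard
quantification (AP line profile, center background subtraction, half-max
domain width and polar domain amplitude), and compares the measured
widths with the generator's analytic half-max boundaries.
"""

import embryograd as eg

print(f"{'stage':>6} {'width post (%EL)':>17} {'analytic':>9} {'amp post (AU)':>14} {'bg (AU)':>8}")
backgrounds = {}
for stage in ("NC11", "NC12", "NC13", "NC14"):
    cfg = eg.SceneConfig(nc_stage=stage, seed=1)
    scene, truth = eg.render_embryo(cfg)
    prof = eg.ap_line_profile(
        scene, truth.geometry, channel="ztsh2", exclude_mask=truth.exclusion_mask()
    )
    sub = eg.subtract_center_background(prof)
    m = eg.compute_domain_metrics(sub)
    gp = cfg.torso_pair[1]
    analytic = gp.half_max_um * 100.0 / cfg.embryo_length_um
    backgrounds[stage] = sub.provenance["center_background_au"]
    print(
        f"{stage:>6} {m.width_posterior_pct_el:>17.1f} {analytic:>9.2f}"
        f" {m.amplitude_posterior_au:>14.1f} {backgrounds[stage]:>8.1f}"
    )

ratios = eg.normalize_background_series(backgrounds)
print("\ncytosolic background relative to NC11:",
      {k: round(v, 2) for k, v in ratios.items()})
print(
    "\nThe activity domain narrows and its amplitude collapses over the"
    "\nnuclear cycles while the cytosolic biosensor background rises -"
    "\nthe receptor-level picture the pipeline is built to measure."
)
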