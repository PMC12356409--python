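"""Perimeter scan of a sagittal slice: two polar activity peaks.

The perimeter profile samples a 5 px band just inside the embryo
boundary (next to, but not overlapping, the autofluorescent vitelline
ring), binned by arc length from the dorsal starting point.  Peak
counting distinguishes wild-type (two polar peaks) from a terminal-system
mutant (none) and a single-pole construct (one).
"""

import numpy as np

import embryograd as eg

zero = eg.GradientParams(10.0, 10.0, 0.0)
post = eg.GradientParams(25.0, 20.0, 150.0)
variants = {
    "wild type": eg.SceneConfig(nc_stage="NC12", view="sagittal", seed=2),
    "tsl-like (no terminal activity)": eg.SceneConfig(torso=zero, erk=zero, view="sagittal", seed=2),
    "posterior-only construct": eg.SceneConfig(torso=(zero, post), erk=(zero, post), view="sagittal", seed=2),
}
for name, cfg in variants.items():
    scene, truth = eg.render_embryo(cfg)
    prof = eg.perimeter_profile(
        scene, truth.geometry, channel="ztsh2", contour_mask=truth.embryo_mask
    )
    n = eg.count_pole_peaks(prof)
    bin_ant, bin_post = prof.provenance["pole_bins"]
    print(f"{name:35s} peaks={n}  (pole arc bins: anterior {bin_ant}, posterior {bin_post};"
          f" profile max {np.nanmax(prof.values):.0f} AU)")

print("\nPeaks are local maxima of the circular profile above half of its"
      "\ndynamic range; a flat profile reports zero peaks.")
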