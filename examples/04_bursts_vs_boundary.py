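"""Transcription bursts extend beyond the receptor-activity boundary.

Bursts of a posterior target gene are placed wherever the broader
downstream gradient stays above half of its pole value, re-detected from
the rendered spot channel, and compared with the receptor half-max
boundary measured by the profile pipeline: the gap quantifies how much
farther downstream signaling reaches than receptor activity.
"""

import numpy as np

import embryograd as eg

torso = eg.GradientParams(25.0, 20.0, 150.0)
erk = eg.GradientParams(25.0, 92.0, 150.0)
positions = tuple(float(d) for d in np.arange(0, 250, 5.0) if erk(d) >= 0.5 * erk(0.0))
cfg = eg.SceneConfig(torso=torso, erk=erk, cytosol_background=60.0, seed=4,
                     burst_positions_um=positions)
scene, truth = eg.render_embryo(cfg)

prof = eg.subtract_center_background(
    eg.ap_line_profile(scene, truth.geometry, channel="ztsh2",
                       exclude_mask=truth.exclusion_mask())
)
width_pct = eg.domain_width(prof, "posterior")
boundary_um = width_pct / 100.0 * truth.geometry.embryo_length_um

bursts = eg.detect_bursts(scene, threshold_au=150.0, geometry=truth.geometry, channel="ms2")
edges, counts = bursts.histogram()

print(f"receptor half-max boundary: {boundary_um:.0f} um from the posterior pole")
print(f"bursts detected: {len(bursts)} (placed: {len(positions)})")
print(f"farthest burst: {bursts.max_distance_um():.0f} um")
print(f"gap beyond receptor boundary: {bursts.max_distance_um() - boundary_um:.0f} um")
print("burst counts per 5 um bin:", counts.tolist())
print("\nThe ~45 um gap shows a downstream gradient reaching well past the"
      "\nnarrow domain of receptor activity.")
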