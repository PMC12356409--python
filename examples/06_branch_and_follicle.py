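"""Accessory readouts: tiled colocalization and apical enrichment.

Tracheal branch: receptor activity is restricted to the leading tip
cells, detected as Pearson correlation between the biosensor and a
membrane marker in 4.5 um boxes tiled stalk-to-tip.  Follicle epithelium:
receptor activity on the dorsal side shows as apical-membrane enrichment
of the biosensor over the apical cytoplasm.
"""

import numpy as np

import embryograd as eg

# --- branch colocalization -------------------------------------------
scene = eg.render_branch(n_boxes=8, tip_active=True, seed=6)
h, w = scene.pixels.shape[-2:]
half_box = 0.5 * 4.5 / scene.pixel_size_um
axis = ((h / 2, half_box), (h / 2, w - half_box))
pr = eg.tiled_pearson(
    scene.plane("biosensor"), scene.plane("membrane"), axis, 8,
    pixel_size_um=scene.pixel_size_um,
)
print("per-box Pearson r, stalk -> tip:", np.round(pr.correlations, 2).tolist())
print(f"tip box r = {pr.correlations[-1]:.2f} vs stalk box r = {pr.correlations[0]:.2f}")

# --- follicle apical enrichment --------------------------------------
fol = eg.render_follicle(dorsal_active=True, seed=6)
px = fol.pixel_size_um
wf = fol.pixels.shape[-1]
apical_line = np.array([(3.7 / px, 2.0), (3.7 / px, wf - 3.0)])
cyto_line = np.array([(6.5 / px, 2.0), (6.5 / px, wf - 3.0)])
ratio = eg.apical_enrichment(fol.plane(), apical_line, cyto_line, line_width_px=3)
k = len(ratio) // 3
print(f"\napical/cytoplasm ratio: dorsal {np.nanmean(ratio[:k]):.2f},"
      f" ventral {np.nanmean(ratio[-k:]):.2f}")
print("\nBiosensor-membrane correlation only in the active tip segment, and"
      "\napical enrichment only on the active (dorsal) side.")
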