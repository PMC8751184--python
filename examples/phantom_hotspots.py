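"""Hotspot map of a layered torso phantom under front-to-back exposure.

Builds the elliptical layered phantom, assigns Cole-Cole conductivities,
solves the induced field for a 0.3 mT, 1 kHz front-to-back exposure,
applies the 5-mm line-averaging rule, and lists the top averaged-field
positions in fat/skin — the sites where peripheral-nerve fibers are
seeded in the full pipeline.
"""

import numpy as np

from pnstim import (ExposureSpec, assign_conductivity, line_average,
                    load_cole_cole_table, make_layered_cylinder,
                    percentile_filter, solve_field, top_hotspots)

grid = make_layered_cylinder(radius_mm=120.0, height_mm=40.0,
                             voxel_size_mm=2.0,
                             layer_thicknesses={"skin": 2.0, "fat": 10.0})
cond = assign_conductivity(grid, load_cole_cole_table(), 1000.0)
expo = ExposureSpec(b_amplitude_t=0.3e-3, direction=(0, 1, 0),
                    frequency_hz=1000.0)
field = solve_field(cond, expo)
print(f"solved {grid.shape} grid, residual {field.residual:.1e}")

avg = line_average(field, grid)
fat = grid.labels == grid.label_of("fat")
print(f"99th-percentile line-averaged |E| in fat: "
      f"{percentile_filter(avg[fat], 99):.4f} V/m (peak, at 0.3 mT)")

hs = top_hotspots(avg, grid, tissues=("fat", "skin"), n=5,
                  min_separation_mm=15.0, method="line5mm")
print(f"\ntop {len(hs)} hotspots (>=15 mm apart):")
for h in hs.entries:
    x, y, z = h.world_mm
    print(f"  ({x:7.1f}, {y:7.1f}, {z:5.1f}) mm  {h.value:.4f} V/m  "
          f"[{h.tissue}]")
print("\nHotspots sit on the lateral flanks, where the induced current "
      "loops of a\nfront-to-back field run fastest — these positions seed "
      "the fiber population.")
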