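"""Reconstruct a foot-pressure heatmap from one mid-stance frame.

The 16 sensor percents seed 32 cells of the 10x22 foot-shaped grid (each
film sensor covers two vertically adjacent squares); the remaining footprint
cells are filled by repeated synchronous eight-nearest-neighbor averaging.
"""

import numpy as np

from baropod import default_layout, fill_grid, render_grid, seed_grid, simulate_session
from baropod.simulate import RunnerProfile, SimConfig

session = simulate_session(RunnerProfile(), SimConfig(duration_ms=5_000, random_seed=4))
# pick the left-foot frame with the highest total pressure (mid-stance)
frame = max(session.left, key=lambda v: sum(v.values))
print(f"frame at t={frame.timestamp_ms} ms, sensor percents: {frame.values}")

layout = default_layout()
grid = fill_grid(seed_grid(layout, frame))
inside = grid.values[layout.footprint_mask]
print(f"footprint cells: {inside.size}, seeded: 32, "
      f"filled range: {inside.min():.1f}-{inside.max():.1f}%")

pgm, png = render_grid(grid, "scratch_heatmap", palette="viridis")
print(f"wrote {pgm} and {png}")
print()
print("Filled values never leave the range spanned by the sensor values")
print("(neighbor averaging obeys a maximum principle).")
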