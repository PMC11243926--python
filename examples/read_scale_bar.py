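"""Read temperatures off a thermal image's colour scale bar.

The bar is the only calibration in a screen-recorded thermal view: its top
row is the frame's maximum temperature, its bottom row the minimum, and
every row in between interpolates linearly.  This example renders a bar
with the endpoints 29.3 / 50.5 deg C and reads temperatures back by colour.
"""

import numpy as np

from lizardtherm import PixelCoord, ScaleBar, colour_to_temperature, make_colourmap, row_to_temperature

bar = ScaleBar(t_min=29.3, t_max=50.5, y_min=20, y_max=100, x_med=30, bar_width=10)

# paint the bar into an otherwise empty thermal-style panel
panel = np.zeros((130, 60, 3), np.uint8)
cmap = make_colourmap(bar.n_rows)
x0, x1 = bar.columns()
for y in range(bar.y_min, bar.y_max + 1):
    panel[y, x0:x1] = cmap[bar.y_max - y]

for name, row in [("bottom (cold end)", bar.y_max),
                  ("middle", (bar.y_min + bar.y_max) // 2),
                  ("top (hot end)", bar.y_min)]:
    t = colour_to_temperature(panel, bar, PixelCoord(bar.x_med, row))
    print(f"{name:18s} row {row:3d} -> {t:.1f} deg C (formula: {row_to_temperature(bar, row):.1f})")

print(f"\nquantisation step: {bar.step:.3f} deg C per bar row")
# The colour lookup and the interpolation formula agree row for row; the
# step is the resolution limit of any reading taken through the bar.
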