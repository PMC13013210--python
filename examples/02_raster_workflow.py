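"""Raster workflow: two input grids -> SSI surface -> comfort classes.

Mirrors the map-algebra core of the toolkit: align-checked elementwise
SSI with nodata propagation, categorical classification, and per-class
area shares.
"""

import numpy as np

from simmermap import Grid, class_area_fractions, classify_grid, ssi_grid, table1_scheme

transform = (500_000.0, 250.0, 0.0, 4_100_000.0, 0.0, -250.0)  # 250 m pixels
crs = "EPSG:32636"

# a south-north temperature gradient (degC) and its humidity counterpart
rows, cols = 80, 80
gradient = np.linspace(1.0, 0.0, rows)[:, None] * np.ones((1, cols))
temp = Grid((22.0 + 12.0 * gradient).astype(np.float32), transform, crs)
rh = Grid((45.0 + 30.0 * gradient).astype(np.float32), transform, crs)

ssi = ssi_grid(temp, rh, in_unit="C", out_unit="F")
classes = classify_grid(ssi, table1_scheme())

print(f"SSI range: {ssi.values.min():.1f} - {ssi.values.max():.1f} degF")
print("share of map area per comfort class:")
for code, pct in sorted(class_area_fractions(classes).items()):
    cat = table1_scheme().by_code(code)
    print(f"  [{code}] {cat.label:<14} {pct:5.1f} %")

# Hot humid lowlands in the south classify Sweltering while the cooler,
# drier north stays at or below Comfortable — the classic coastal-city
# summer contrast the index is designed to expose.
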