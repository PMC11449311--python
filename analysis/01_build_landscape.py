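"""Build and scale the synthetic rangeland covariate stack.

Writes the raw layers as ASCII grids plus a summary of their ranges and the
centering/scaling constants, and checks the wet-season boma vacating and the
dist_water/dist_human correlation that motivates dropping distance-to-water
from the model formulas.
"""

import importlib.util
import json
import sys
from pathlib import Path

import numpy as np
import shapely

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    out = common.OUT / "landscape"
    out.mkdir(parents=True, exist_ok=True)
    stack_raw, stack, points, area, vacate = common.landscape()

    rows = []
    for name, grid in stack_raw.layers.items():
        grid.write_ascii(out / f"{name}.asc")
        vals = grid.values[~grid.is_nodata()]
        rows.append(f"{name}: range [{vals.min():.2f}, {vals.max():.2f}], mean {vals.mean():.2f}")
    (out / "layer_summary.txt").write_text("\n".join(rows) + "\n")
    json.dump({k: list(v) for k, v in stack.scaling.items()}, open(out / "scaling.json", "w"), indent=1)

    dry_in = shapely.contains(vacate, shapely.points(points["bomas_dry"].points)).sum()
    wet_in = shapely.contains(vacate, shapely.points(points["bomas_wet"].points)).sum()
    dw = stack_raw.layers["dist_water"].values.ravel()
    dh = stack_raw.layers["dist_human_dry"].values.ravel()
    corr = float(np.corrcoef(dw, dh)[0, 1])
    print(f"landscape: {len(stack_raw.layers)} layers on {stack_raw.template.values.shape} cells")
    print(f"bomas in western plains: dry {dry_in}, wet {wet_in} (herders vacate in the rains)")
    print(f"corr(dist_water, dist_human_dry) = {corr:.2f}; dist_water excluded from model formulas")


if __name__ == "__main__":
    main()
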