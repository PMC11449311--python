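"""RSS curves from the top step-selection model and seasonal resistance
surfaces (1 - RSS summed over covariates; linear-fit and exponential modes,
signed-log display transform)."""

import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import lionhab.rss as rss
from lionhab.design import ModelFit


def main():
    warnings.filterwarnings("ignore")
    out = common.OUT
    fit = ModelFit.from_json(out / "ssf_top_fit.json")
    _, stack, *_ = common.landscape()
    main_terms = [t for t in fit.terms if ":" not in t]
    layer_map = {"dens_human": "dens_human_3km"}
    for season in ("wet", "dry"):
        curves = [rss.rss_curve(fit, t, stack, season, layer_name=layer_map.get(t)) for t in main_terms]
        json.dump(rss.curves_to_json_dict(curves), open(out / f"rss_curves_{season}.json", "w"), indent=1)
        for mode in ("linear_fit", "exact_exp"):
            surf = rss.resistance_surface(curves, stack, season, mode=mode, provenance={"model": fit.extra.get("model_name")})
            suffix = "" if mode == "linear_fit" else "_exp"
            surf.raster.write_ascii(out / f"resistance_{season}{suffix}.asc")
            surf.display.write_ascii(out / f"resistance_{season}{suffix}_display.asc")
        vals = surf.raster.values[~surf.raster.is_nodata()]
        print(f"{season}: resistance range [{vals.min():.2f}, {vals.max():.2f}], mean {vals.mean():.2f}")


if __name__ == "__main__":
    main()
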