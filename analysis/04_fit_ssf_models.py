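"""Step-selection model competition: the six candidate formulations ranked
by AIC, the top model refit, and season x diel stratified refits."""

import importlib.util
import warnings
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import lionhab.ssf as ssf


def main():
    warnings.filterwarnings("ignore")
    out = common.OUT
    data = ssf.with_density_radius(pd.read_csv(out / "ssf_data.csv"), 3.0)
    fits = {c.name: ssf.fit_ssf_poisson(data, c) for c in ssf.candidate_model_set()}
    table = ssf.rank_by_aic(fits)
    table.to_csv(out / "ssf_model_selection.csv", index=False)
    print(table.to_string(index=False))
    top = table["model"].iloc[0]
    top_fit = fits[top]
    top_fit.to_json(out / "ssf_top_fit.json")
    print(f"\ntop model: {top}")
    print(top_fit.summary_frame().to_string(index=False))
    cand = next(c for c in ssf.candidate_model_set() if c.name == top)
    for season in ("wet", "dry"):
        for diel in ("day", "night"):
            sub = data[(data["season"] == season) & (data["diel"] == diel)]
            if sub["stratum_id"].nunique() < 30:
                continue
            fit = ssf.fit_ssf_poisson(sub, cand)
            fit.to_json(out / f"ssf_fit_{season}_{diel}.json")
            print(f"{season}/{diel}: {sub['stratum_id'].nunique()} strata, cover slope {fit.estimates['cover']:.2f}")


if __name__ == "__main__":
    main()
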