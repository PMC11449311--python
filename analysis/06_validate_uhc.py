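"""Used-habitat calibration of the top step-selection model: stratum-level
train/test split, 1000 coefficient draws, per-covariate envelope plots."""

import importlib.util
import json
import warnings
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import lionhab.ssf as ssf
import lionhab.uhc as uhc


def main():
    warnings.filterwarnings("ignore")
    out = common.OUT
    data = ssf.with_density_radius(pd.read_csv(out / "ssf_data.csv"), 3.0)
    table = pd.read_csv(out / "ssf_model_selection.csv")
    cand = next(c for c in ssf.candidate_model_set() if c.name == table["model"].iloc[0])
    train, test = uhc.uhc_split(data, seed=common.SEED + 3)
    fit = ssf.fit_ssf_poisson(train, cand)
    res = uhc.uhc_simulate(fit, test, n_draws=1000, seed=common.SEED + 4)
    for cov, frame in uhc.uhc_result_frames(res).items():
        frame.to_csv(out / f"uhc_{cov}.csv", index=False)
    uhc.uhc_plot(res, out / "uhc_plots.png")
    json.dump(res.coverage_fraction, open(out / "uhc_coverage.json", "w"), indent=1)
    print("envelope coverage by covariate (fraction of grid points):")
    for c, v in res.coverage_fraction.items():
        print(f"  {c}: {v:.3f}")


if __name__ == "__main__":
    main()
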