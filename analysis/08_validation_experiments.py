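"""Run the full validation battery (the same experiments the acceptance
script reports) and write one tidy table of headline quantities."""

import json
import warnings
from pathlib import Path

import lionhab.experiments as ex


def main():
    warnings.filterwarnings("ignore")
    out = Path(__file__).resolve().parent.parent / "results" / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    results = {
        "oracle_equivalence": ex.oracle_equivalence(seed=1),
        "ssf_recovery": ex.ssf_recovery(seed=1, n_replicates=20),
        "rsf_recovery": ex.rsf_recovery(seed=1, n_replicates=20),
        "rss_identities": ex.rss_identities(seed=1),
        "uhc_calibration": ex.uhc_calibration(seed=1),
        "radius_identification": ex.radius_identification(seed=1, n_replicates=20),
        "diel_agreement": ex.diel_agreement(),
        "msd_behavior": ex.msd_behavior(seed=1),
    }
    json.dump(results, open(out / "validation_experiments.json", "w"), indent=1, default=float)
    for name, res in results.items():
        print(f"{name}:")
        for k, v in res.items():
            if isinstance(v, (int, float, bool)):
                print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
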