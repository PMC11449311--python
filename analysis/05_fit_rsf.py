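"""Landscape-scale resource selection: 12-h resampling, study-area clipping,
100:1 availability, weighted (1000) mixed logistic fits per season."""

import importlib.util
import warnings
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import lionhab.rsf as rsf
import lionhab.trajectory as tj


def main():
    warnings.filterwarnings("ignore")
    out = common.OUT
    out.mkdir(parents=True, exist_ok=True)
    _, stack, _, area, _ = common.landscape()
    track = common.tracks(stack)
    for season in ("wet", "dry"):
        sub = track[track["season"] == season]
        used = tj.clip_to_study_area(tj.resample_track(sub, 12.0, 120.0), area)
        if len(used) < 10:
            print(f"{season}: too few 12-h fixes ({len(used)}), skipped")
            continue
        data = rsf.sample_available_rsf(area, used, stack, ratio=100, seed=common.SEED + 2)
        fit = rsf.fit_rsf(data)
        fit.to_json(out / f"rsf_fit_{season}.json")
        print(f"\n{season} season RSF ({len(used)} used fixes, {len(data)} rows):")
        print(fit.summary_frame().to_string(index=False))


if __name__ == "__main__":
    main()
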