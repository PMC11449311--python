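"""Shared settings for the numbered analysis scripts.

Every script regenerates its inputs deterministically from SEED via the
library, so each can be run on its own; outputs accumulate under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lionhab as lh
import lionhab.trajectory as tj

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
EXTENT = (20_000.0, 20_000.0)
CELL = 200.0
N_ANIMALS = 4
N_STEPS = 400
TRUE_BETA = {"cover": 0.8, "tri": -0.3, "evi": 0.3, "dist_river": -0.4, "dist_human": 0.5, "dens_human_3km": -0.4}
KERNEL = lh.MovementKernel(2.0, 300.0, 0.0, 0.5)


def landscape():
    stack_raw, points, area, vacate = lh.generate_synthetic_landscape(SEED, EXTENT, CELL)
    return stack_raw, lh.scale_covariates(stack_raw), points, area, vacate


def tracks(stack):
    """Deterministic demo herd: half wet-season starts, half dry."""
    rng = np.random.default_rng(SEED)
    coeffs = lh.SelectionCoefficients(beta=dict(TRUE_BETA))
    out = []
    for i in range(N_ANIMALS):
        # one wet-season and one dry-season segment per animal, so the
        # seasonal MSD contrast is estimable
        for t0 in ("2023-01-10T00:00:00Z", "2023-07-10T00:00:00Z"):
            start = (rng.uniform(5000, 15000), rng.uniform(5000, 15000))
            out.append(
                lh.simulate_ssf_track(
                    stack, KERNEL, coeffs, start, N_STEPS, seed=int(rng.integers(2**31)), animal_id=f"lion{i:02d}", start_time=t0
                )
            )
    track = pd.concat(out, ignore_index=True)
    track = tj.annotate_season(track)
    return tj.annotate_diel(track, ref_lon=35.0, ref_lat=-3.0)
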