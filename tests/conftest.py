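import numpy as np
import pandas as pd
import pytest

import lionhab as lh


@pytest.fixture(scope="session")
def bundle():
    """One synthetic landscape shared across tests (raw stack + geometry)."""
    stack_raw, points, area, vacate = lh.generate_synthetic_landscape(
        seed=2, extent=(20_000.0, 20_000.0), cell_size=200.0
    )
    return stack_raw, points, area, vacate


@pytest.fixture(scope="session")
def stack(bundle):
    return lh.scale_covariates(bundle[0])


@pytest.fixture(scope="session")
def kernel():
    return lh.MovementKernel(2.0, 300.0, 0.0, 0.5)


@pytest.fixture(scope="session")
def hourly_track():
    rng = np.random.default_rng(11)
    n = 200
    return pd.DataFrame(
        {
            "animal_id": "a",
            "timestamp": pd.date_range("2023-01-01", periods=n, freq="h", tz="UTC"),
            "x": np.cumsum(rng.normal(0, 300, n)),
            "y": np.cumsum(rng.normal(0, 300, n)),
        }
    )


@pytest.fixture(scope="session")
def ssf_dataset(stack, kernel):
    """A small stratified used/available dataset from one simulated track."""
    import lionhab.ssf as ssf
    import lionhab.trajectory as tj

    coeffs = lh.SelectionCoefficients(beta={"cover": 0.8, "dist_human": 0.5})
    rng = np.random.default_rng(3)
    tracks = [
        lh.simulate_ssf_track(
            stack,
            kernel,
            coeffs,
            (rng.uniform(6000, 14000), rng.uniform(6000, 14000)),
            250,
            seed=int(rng.integers(2**31)),
            animal_id=f"a{i}",
        )
        for i in range(3)
    ]
    steps = tj.build_steps(pd.concat(tracks, ignore_index=True), 1.0, 30.0)
    return ssf.sample_available_steps(steps, kernel, stack, k=20, seed=5)
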