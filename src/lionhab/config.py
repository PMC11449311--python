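"""Analysis configuration: every tunable the pipeline uses, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    """Settings for the end-to-end habitat-selection pipeline.

    Defaults reproduce the study conditions: 100 available points per used
    RSF location at weight 1000, 50 available steps per stratum, random
    intercept variances fixed at 10^3, boma-density radii of 1/3/5 km,
    wet season Dec-May, 12-h RSF resampling, 1000 UHC draws and a 200-point
    RSS grid.
    """

    seed: int = 1
    # landscape
    extent_m: tuple = (30_000.0, 30_000.0)
    cell_size_m: float = 200.0
    # simulation (demo tracks)
    n_animals: int = 3
    n_steps: int = 500
    fix_interval_hours: float = 1.0
    gamma_shape: float = 2.0
    gamma_scale_m: float = 300.0
    vm_kappa: float = 0.5
    beta: dict = field(
        default_factory=lambda: {
            "cover": 0.8,
            "tri": -0.3,
            "evi": 0.3,
            "dist_river": -0.4,
            "dist_human": 0.5,
            "dens_human_3km": -0.4,  # generative truth acts on the 3-km density layer
        }
    )
    individual_sd: float = 0.0  # sd of per-animal coefficient deviations
    # trajectory prep
    rsf_resample_hours: float = 12.0
    rsf_resample_tolerance_min: float = 120.0
    ssf_step_hours: float = 1.0
    ssf_step_tolerance_min: float = 30.0
    ref_lon: float = 35.0  # study-area reference for solar geometry
    ref_lat: float = -3.0
    # models
    rsf_ratio: int = 100
    rsf_weight: float = 1000.0
    ssf_k_available: int = 50
    fixed_intercept_variance: float = 1e3
    density_radii_km: tuple = (1.0, 3.0, 5.0)
    random_slopes: bool = False
    # validation / mapping
    uhc_draws: int = 1000
    rss_grid: int = 200
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.rsf_ratio < 1 or self.ssf_k_available < 1:
            raise ValueError("availability ratios must be >= 1")
        if self.rsf_weight <= 0 or self.fixed_intercept_variance <= 0:
            raise ValueError("weights and variances must be positive")

    def to_yaml(self, path=None) -> str:
        txt = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        for key in ("extent_m", "density_radii_km"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)
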