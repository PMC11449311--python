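"""End-to-end orchestration mirroring the analysis order:

1. landscape build + scaling, 2. track preparation + MSD, 3. boma-density
radius selection, 4. six-model SSF selection with stratified refits,
5. seasonal RSF, 6. UHC validation of the top SSF model, 7. RSS curves and
seasonal resistance rasters.  Every stage logs its seed and row counts and
persists intermediates so later stages can be rerun from disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import landscape as ls
from . import movement, rsf, rss, ssf, trajectory, uhc
from .config import AnalysisConfig

log = logging.getLogger("lionhab")


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: AnalysisConfig) -> Path:
    """Run all seven stages on a synthetic landscape; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    rng = np.random.default_rng(config.seed)

    # -- 1. landscape -------------------------------------------------------
    _stage("landscape")
    stack_raw, points, study_area, vacate = ls.generate_synthetic_landscape(
        seed=config.seed, extent=config.extent_m, cell_size=config.cell_size_m
    )
    stack = ls.scale_covariates(stack_raw)
    for name, grid in stack_raw.layers.items():
        grid.write_ascii(out / f"layer_{name}.asc")
    json.dump(
        {k: list(v) for k, v in stack.scaling.items()},
        open(out / "scaling.json", "w"),
        indent=1,
    )

    # -- 2. tracks + MSD ----------------------------------------------------
    _stage("tracks")
    kernel = trajectory.MovementKernel(config.gamma_shape, config.gamma_scale_m, 0.0, config.vm_kappa)
    beta = dict(config.beta)
    offsets = {}
    tracks = []
    xmin, ymin, xmax, ymax = stack.template.bounds
    for i in range(config.n_animals):
        animal = f"lion{i:02d}"
        if config.individual_sd > 0:
            offsets[animal] = {t: float(rng.normal(0, config.individual_sd)) for t in beta}
        start = (
            float(rng.uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))),
            float(rng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))),
        )
        coeffs = movement.SelectionCoefficients(beta=beta, individual_offsets=offsets)
        # alternate wet/dry starts so both seasons appear
        start_time = "2023-01-10T00:00:00Z" if i % 2 == 0 else "2023-07-10T00:00:00Z"
        tracks.append(
            movement.simulate_ssf_track(
                stack,
                kernel,
                coeffs,
                start,
                config.n_steps,
                config.fix_interval_hours,
                seed=int(rng.integers(2**31)),
                animal_id=animal,
                start_time=start_time,
            )
        )
    track = pd.concat(tracks, ignore_index=True)
    track = trajectory.annotate_season(track)
    track = trajectory.annotate_diel(track, config.ref_lon, config.ref_lat)
    trajectory.write_track_csv(track, out / "tracks.csv")
    msd_tab = trajectory.msd_table(track)
    msd_tab.to_csv(out / "msd.csv", index=False)
    log.info("tracks: %d fixes, %d animals", len(track), config.n_animals)

    # -- 3/4. steps, radius selection, model selection ---------------------
    _stage("steps")
    steps = trajectory.build_steps(track, config.ssf_step_hours, config.ssf_step_tolerance_min)
    steps = steps.merge(
        track[["animal_id", "timestamp", "season", "diel"]],
        left_on=["animal_id", "t_end"],
        right_on=["animal_id", "timestamp"],
        how="left",
    ).drop(columns="timestamp")
    fitted_kernel = trajectory.fit_movement_kernel(steps)
    data = ssf.sample_available_steps(
        steps,
        fitted_kernel,
        stack,
        k=config.ssf_k_available,
        seed=config.seed + 1,
        dens_radii_km=config.density_radii_km,
    )
    data.to_csv(out / "ssf_data.csv", index=False)

    _stage("radius-selection")
    radius, radius_table = ssf.select_density_radius(data, config.density_radii_km)
    radius_table.to_csv(out / "radius_selection.csv", index=False)
    data_r = ssf.with_density_radius(data, radius)
    log.info("chosen density radius: %g km", radius)

    _stage("ssf-model-selection")
    fits = {}
    rs_terms = ssf.DEFAULT_TERMS if config.random_slopes else None
    for cand in ssf.candidate_model_set():
        fits[cand.name] = ssf.fit_ssf_poisson(data_r, cand, random_slopes=None)
    aic_table = ssf.rank_by_aic(fits)
    aic_table.to_csv(out / "ssf_model_selection.csv", index=False)
    top_name = aic_table["model"].iloc[0]
    top_cand = next(c for c in ssf.candidate_model_set() if c.name == top_name)
    top_fit = ssf.fit_ssf_poisson(
        data_r, top_cand, random_slopes=(top_cand.terms if config.random_slopes else None)
    )
    top_fit.to_json(out / "ssf_top_fit.json")
    # stratified refits: season x diel
    strat_fits = {}
    for season in ("wet", "dry"):
        for diel in ("day", "night"):
            sub = data_r[(data_r["season"] == season) & (data_r["diel"] == diel)]
            if sub["stratum_id"].nunique() >= 30:
                try:
                    strat_fits[f"{season}_{diel}"] = ssf.fit_ssf_poisson(sub, top_cand)
                except ValueError as exc:
                    log.warning("stratified fit %s_%s skipped: %s", season, diel, exc)
    for key, fit in strat_fits.items():
        fit.to_json(out / f"ssf_fit_{key}.json")
    log.info("top SSF model: %s", top_name)

    # -- 5. RSF per season --------------------------------------------------
    _stage("rsf")
    rsf_fits = {}
    for season in ("wet", "dry"):
        sub = track[track["season"] == season]
        if sub.empty:
            continue
        used = trajectory.clip_to_study_area(
            trajectory.resample_track(sub, config.rsf_resample_hours, config.rsf_resample_tolerance_min),
            study_area,
        )
        if len(used) < 10:
            continue
        rsf_data = rsf.sample_available_rsf(
            study_area, used, stack, ratio=config.rsf_ratio, seed=config.seed + 2, dens_radius_km=radius
        )
        rsf_fits[season] = rsf.fit_rsf(
            rsf_data,
            available_weight=config.rsf_weight,
            random_slopes=(rsf.DEFAULT_TERMS if config.random_slopes else None),
        )
        rsf_fits[season].to_json(out / f"rsf_fit_{season}.json")

    # -- 6. UHC -------------------------------------------------------------
    _stage("uhc")
    train, test = uhc.uhc_split(data_r, seed=config.seed + 3)
    train_fit = ssf.fit_ssf_poisson(train, top_cand)
    uhc_result = uhc.uhc_simulate(train_fit, test, n_draws=config.uhc_draws, seed=config.seed + 4)
    for cov, frame in uhc.uhc_result_frames(uhc_result).items():
        frame.to_csv(out / f"uhc_{cov}.csv", index=False)
    uhc.uhc_plot(uhc_result, out / "uhc_plots.png")
    json.dump(uhc_result.coverage_fraction, open(out / "uhc_coverage.json", "w"), indent=1)

    # -- 7. RSS + resistance -----------------------------------------------
    _stage("resistance")
    main_terms = [t for t in top_fit.terms if ":" not in t]
    layer_map = {"dens_human": f"dens_human_{radius:g}km"}
    for season in ("wet", "dry"):
        curves = [
            rss.rss_curve(top_fit, t, stack, season, config.rss_grid, layer_name=layer_map.get(t))
            for t in main_terms
        ]
        surf = rss.resistance_surface(curves, stack, season, provenance={"model": top_name})
        surf.raster.write_ascii(out / f"resistance_{season}.asc")
        surf.display.write_ascii(out / f"resistance_{season}_display.asc")
        json.dump(rss.curves_to_json_dict(curves), open(out / f"rss_curves_{season}.json", "w"), indent=1)

    log.info("pipeline complete -> %s", out)
    return out
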