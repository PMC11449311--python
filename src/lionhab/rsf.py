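"""Landscape-scale resource-selection functions.

Used locations (12-h resampled, clipped to the study area) are contrasted
with uniform random available locations (100 per used fix) via a weighted
logistic regression: available rows carry a large weight (1000) so the fit
approximates the point-process likelihood of the RSF.  A per-animal random
intercept has its variance fixed at 10^3; per-animal random slopes (diagonal
covariance) can be added with estimated variances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from . import fitting
from .design import ModelFit, base_covariates, term_matrix
from .landscape import CovariateStack, extract_matrix

AVAILABLE_RATIO = 100
AVAILABLE_WEIGHT = 1000.0
FIXED_INTERCEPT_VARIANCE = 1e3
DEFAULT_TERMS = ["cover", "tri", "evi", "dist_river", "dist_human", "dens_human"]


def sample_available_rsf(
    study_area,
    used: pd.DataFrame,
    stack: CovariateStack,
    ratio: int = AVAILABLE_RATIO,
    seed: int = 0,
    covariates=None,
    dens_radius_km: float = 3.0,
    max_tries: int = 500,
) -> pd.DataFrame:
    """Uniform random available locations in the study area, ``ratio`` per
    used fix, each inheriting its used fix's animal/season/diel tags.

    Points on nodata cells are rejected.  ``used`` must carry animal_id, x,
    y, season (diel optional).
    """
    if not stack.scaling:
        raise ValueError("stack must be scaled")
    names = covariates or ["cover", "tri", "evi", "dist_river", "dist_human", f"dens_human_{dens_radius_km:g}km"]
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = study_area.bounds
    n_avail = ratio * len(used)
    pts = np.empty((0, 2))
    season_probe = used["season"].iloc[0]
    for _ in range(max_tries):
        need = n_avail - len(pts)
        if need <= 0:
            break
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, 2 * need), rng.uniform(ymin, ymax, 2 * need)]
        )
        inside = shapely.contains(study_area, shapely.points(cand))
        cand = cand[inside & stack.template.contains(cand[:, 0], cand[:, 1])]
        if len(cand):
            vals = extract_matrix(stack, cand[:, 0], cand[:, 1], np.full(len(cand), season_probe), names)
            cand = cand[~np.isnan(vals).any(axis=1)]
        pts = np.vstack([pts, cand])
    if len(pts) < n_avail:
        raise ValueError("study area appears to be fully nodata; cannot sample availability")
    pts = pts[:n_avail]

    used_rows = used.reset_index(drop=True)
    rows = []
    for i, fix in used_rows.iterrows():
        tag = {
            "animal_id": fix["animal_id"],
            "season": fix["season"],
            "diel": fix.get("diel", "unset"),
        }
        rows.append(tag | {"case": 1, "x": fix["x"], "y": fix["y"]})
        block = pts[i * ratio : (i + 1) * ratio]
        for p in block:
            rows.append(tag | {"case": 0, "x": p[0], "y": p[1]})
    data = pd.DataFrame(rows)
    vals = extract_matrix(
        stack, data["x"].to_numpy(), data["y"].to_numpy(), data["season"].to_numpy(), names
    )
    for j, nm in enumerate(names):
        data[nm] = vals[:, j]
    dens_col = f"dens_human_{dens_radius_km:g}km"
    if dens_col in data.columns:
        data["dens_human"] = data[dens_col]
    if data[names].isna().any().any():
        data = data.dropna(subset=names).reset_index(drop=True)
    return data


def fit_rsf(
    data: pd.DataFrame,
    terms=None,
    available_weight: float = AVAILABLE_WEIGHT,
    fixed_intercept_variance: float = FIXED_INTERCEPT_VARIANCE,
    random_slopes=None,
    min_animals_for_slopes: int = 3,
) -> ModelFit:
    """Weighted mixed logistic RSF fit.

    Used rows have weight 1 and available rows ``available_weight`` (the
    "infinitely weighted" logistic device).  The per-animal random intercept
    variance is fixed, random-slope variances are estimated by Laplace.  The
    global intercept is reported but availability-ratio dependent.
    """
    terms = list(terms or DEFAULT_TERMS)
    y = data["case"].to_numpy(dtype=float)
    w = np.where(y == 1, 1.0, available_weight)
    animals = data["animal_id"].to_numpy()
    uniq = np.unique(animals)
    if len(uniq) < 2:
        warnings.warn("fewer than 2 animals: random intercept is weakly identified", stacklevel=2)
    Xf = np.column_stack([np.ones(len(data)), term_matrix(data, terms)])
    fixed_terms = ["(Intercept)"] + terms
    n_fixed = Xf.shape[1]

    # per-animal random intercept columns (fixed variance)
    Z_int = np.column_stack([(animals == a).astype(float) for a in uniq])
    rs_terms = list(random_slopes) if random_slopes else []
    if rs_terms and len(uniq) < min_animals_for_slopes:
        warnings.warn(f"only {len(uniq)} animals; dropping random slopes", stacklevel=2)
        rs_terms = []
    if rs_terms:
        rs_X = term_matrix(data, rs_terms)
        Z_slopes = []
        meta = []
        for j, t in enumerate(rs_terms):
            for a in uniq:
                Z_slopes.append(np.where(animals == a, rs_X[:, j], 0.0))
                meta.append(t)
        Xfull = np.column_stack([Xf, Z_int] + Z_slopes)
        tindex = {t: i for i, t in enumerate(rs_terms)}

        def marginal(variances):
            pen = np.concatenate(
                [
                    np.zeros(n_fixed),
                    np.full(len(uniq), 1.0 / fixed_intercept_variance),
                    np.array([1.0 / variances[tindex[t]] for t in meta]),
                ]
            )
            return fitting.fit_weighted_logistic(Xfull, y, w, pen, n_fixed).loglik_marginal

        variances, _ = fitting.optimize_variances(marginal, len(rs_terms))
        pen = np.concatenate(
            [
                np.zeros(n_fixed),
                np.full(len(uniq), 1.0 / fixed_intercept_variance),
                np.array([1.0 / variances[tindex[t]] for t in meta]),
            ]
        )
        joint = fitting.fit_weighted_logistic(Xfull, y, w, pen, n_fixed)
        random_effects = {"animal_intercept": {"variance": fixed_intercept_variance, "fixed": True}}
        for t in rs_terms:
            random_effects[f"animal_slope:{t}"] = {"variance": float(variances[tindex[t]]), "fixed": False}
    else:
        Xfull = np.column_stack([Xf, Z_int])
        pen = np.concatenate([np.zeros(n_fixed), np.full(len(uniq), 1.0 / fixed_intercept_variance)])
        joint = fitting.fit_weighted_logistic(Xfull, y, w, pen, n_fixed)
        random_effects = {"animal_intercept": {"variance": fixed_intercept_variance, "fixed": True}}

    se = np.sqrt(np.clip(np.diag(joint.vcov_theta)[:n_fixed], 0.0, None))
    return ModelFit(
        terms=fixed_terms,
        estimates={t: float(joint.theta[i]) for i, t in enumerate(fixed_terms)},
        se={t: float(se[i]) for i, t in enumerate(fixed_terms)},
        loglik=float(joint.loglik_marginal),
        n_obs=len(data),
        converged=joint.converged,
        random_effects=random_effects,
        flags=list(joint.flags),
        extra={
            "n_animals": int(len(uniq)),
            "available_weight": available_weight,
            "vcov": joint.vcov_theta[:n_fixed, :n_fixed].tolist(),
            "loglik_data": joint.loglik_data,
        },
    )
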