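"""Local-scale step-selection functions.

Each observed (used) step is matched with K available steps drawn from the
animal's fitted movement kernel (gamma lengths, von Mises turn angles relative
to the previous heading), forming a stratum.  Slopes are estimated with the
Poisson formulation of conditional logistic regression (stratum intercepts as
random effects of fixed variance 10^3, optional per-animal random slopes); an
exact conditional-logistic Newton maximizer serves as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting
from .design import ModelFit, base_covariates, term_matrix
from .landscape import CovariateStack, extract_matrix
from .trajectory import MovementKernel, season_of, wrap_angle

K_AVAILABLE = 50
FIXED_STRATUM_VARIANCE = 1e3
DEFAULT_TERMS = ["cover", "tri", "evi", "dist_river", "dist_human", "dens_human"]
INTERACTION_TERMS = ["cover:dist_human", "cover:dens_human"]


@dataclass
class CandidateModel:
    name: str
    terms: list


def candidate_model_set(interaction_terms=tuple(INTERACTION_TERMS)) -> list:
    """The six competing step-selection formulations."""
    habitat = ["cover", "tri", "evi", "dist_river"]
    human = ["dist_human", "dens_human"]
    return [
        CandidateModel("full", habitat + human),
        CandidateModel("full_interaction", habitat + human + list(interaction_terms)),
        CandidateModel("habitat_only", habitat),
        CandidateModel("human_only", human),
        CandidateModel("cover_only", ["cover"]),
        CandidateModel("habitat_no_cover", ["tri", "evi", "dist_river"]),
    ]


# ---------------------------------------------------------------------------
# Available-step sampling
# ---------------------------------------------------------------------------

def sample_available_steps(
    steps: pd.DataFrame,
    kernel: MovementKernel,
    stack: CovariateStack,
    k: int = K_AVAILABLE,
    seed: int = 0,
    dens_radii_km=(3.0,),
    max_redraw_rounds: int = 100,
) -> pd.DataFrame:
    """Build the stratified used/available dataset for one animal's steps.

    Available endpoints are anchored at each used step's start, with lengths
    from the fitted gamma and turn angles von Mises relative to the previous
    heading (uniform when no previous heading exists).  Season and diel of a
    step are those of its end fix.  Endpoints on nodata are redrawn; a stratum
    that cannot produce K valid endpoints is dropped with a warning.
    """
    if not stack.scaling:
        raise ValueError("stack must be scaled")
    rng = np.random.default_rng(seed)
    names = ["cover", "tri", "evi", "dist_river", "dist_human"] + [f"dens_human_{r:g}km" for r in dens_radii_km]
    rows = []
    dropped = 0
    for _, st in steps.iterrows():
        season = st["season"] if "season" in st and isinstance(st.get("season"), str) else season_of(st["t_end"])
        diel = st.get("diel", "unset")
        prev_heading = (
            wrap_angle(st["heading"] - st["turn_angle"]) if np.isfinite(st.get("turn_angle", np.nan)) else np.nan
        )
        used_vals = extract_matrix(stack, [st["x_end"]], [st["y_end"]], [season], names)[0]
        if np.isnan(used_vals).any():
            dropped += 1
            continue
        ax = np.empty(0)
        ay = np.empty(0)
        for _ in range(max_redraw_rounds):
            need = k - len(ax)
            if need <= 0:
                break
            lengths = np.maximum(rng.gamma(kernel.gamma_shape, kernel.gamma_scale, 2 * need), 1.0)
            if np.isfinite(prev_heading):
                turns = (
                    rng.vonmises(kernel.vm_mu, kernel.vm_kappa, 2 * need)
                    if kernel.vm_kappa > 0
                    else rng.uniform(-np.pi, np.pi, 2 * need)
                )
                angles = wrap_angle(prev_heading + turns)
            else:
                angles = rng.uniform(-np.pi, np.pi, 2 * need)
            px = st["x_start"] + lengths * np.cos(angles)
            py = st["y_start"] + lengths * np.sin(angles)
            ok = stack.template.contains(px, py)
            if ok.any():
                vals = extract_matrix(stack, px[ok], py[ok], np.full(int(ok.sum()), season), names)
                good = ~np.isnan(vals).any(axis=1)
                ax = np.concatenate([ax, px[ok][good]])
                ay = np.concatenate([ay, py[ok][good]])
        if len(ax) < k:
            dropped += 1
            continue
        ax, ay = ax[:k], ay[:k]
        avail_vals = extract_matrix(stack, ax, ay, np.full(k, season), names)
        base = {"stratum_id": st["stratum_id"], "animal_id": st["animal_id"], "season": season, "diel": diel}
        rows.append(base | {"case": 1, "x": st["x_end"], "y": st["y_end"]} | dict(zip(names, used_vals)))
        for i in range(k):
            rows.append(base | {"case": 0, "x": ax[i], "y": ay[i]} | dict(zip(names, avail_vals[i])))
    if dropped:
        warnings.warn(f"dropped {dropped} strata (nodata or boundary redraw failure)", stacklevel=2)
    data = pd.DataFrame(rows)
    if not data.empty and len(dens_radii_km) == 1:
        data["dens_human"] = data[f"dens_human_{dens_radii_km[0]:g}km"]
    return data


def with_density_radius(data: pd.DataFrame, radius_km: float) -> pd.DataFrame:
    """Alias the chosen radius' density column as the model term ``dens_human``."""
    out = data.copy()
    out["dens_human"] = out[f"dens_human_{radius_km:g}km"]
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _terms_of(model) -> tuple[str, list]:
    if isinstance(model, CandidateModel):
        return model.name, list(model.terms)
    return "custom", list(model)


def _check_within_stratum_information(X: np.ndarray, strata: np.ndarray, terms) -> None:
    codes = np.unique(strata, return_inverse=True)[1]
    S = codes.max() + 1
    counts = np.bincount(codes, minlength=S)
    for j, term in enumerate(terms):
        mean = np.bincount(codes, weights=X[:, j], minlength=S) / counts
        if np.max(np.abs(X[:, j] - mean[codes])) < 1e-12:
            raise ValueError(f"covariate {term!r} is constant within every stratum; no information")


def fit_ssf_poisson(
    data: pd.DataFrame,
    model,
    fixed_stratum_variance: float = FIXED_STRATUM_VARIANCE,
    random_slopes=None,
    min_strata: int = 30,
    min_animals_for_slopes: int = 3,
) -> ModelFit:
    """Fit a step-selection model via the Poisson formulation.

    ``random_slopes`` may be None (fixed effects only) or a list of terms to
    give per-animal random slopes (diagonal covariance, variances estimated on
    the Laplace marginal).  Categories with fewer than
    ``min_animals_for_slopes`` animals fall back to fixed effects only.
    """
    name, terms = _terms_of(model)
    strata = data["stratum_id"].to_numpy()
    if len(np.unique(strata)) < min_strata:
        raise ValueError(f"need >= {min_strata} strata")
    X = term_matrix(data, terms)
    _check_within_stratum_information(X, strata, terms)
    y = data["case"].to_numpy(dtype=float)
    animals = data["animal_id"].to_numpy()
    uniq_animals = np.unique(animals)

    rs_terms = list(random_slopes) if random_slopes else []
    if rs_terms and len(uniq_animals) < min_animals_for_slopes:
        warnings.warn(
            f"only {len(uniq_animals)} animals; dropping random slopes", stacklevel=2
        )
        rs_terms = []

    n_fixed = len(terms)
    if rs_terms:
        Z_cols, col_meta = [], []
        rs_X = term_matrix(data, rs_terms)
        for j, term in enumerate(rs_terms):
            for a in uniq_animals:
                Z_cols.append(np.where(animals == a, rs_X[:, j], 0.0))
                col_meta.append(term)
        Xfull = np.column_stack([X] + Z_cols)
        term_index = {t: i for i, t in enumerate(rs_terms)}

        def marginal(variances):
            pen = np.concatenate([np.zeros(n_fixed), np.array([1.0 / variances[term_index[t]] for t in col_meta])])
            fit = fitting.fit_poisson_strata(Xfull, y, strata, pen, fixed_stratum_variance, n_fixed)
            return fit.loglik_marginal

        variances, _ = fitting.optimize_variances(marginal, len(rs_terms))
        pen = np.concatenate([np.zeros(n_fixed), np.array([1.0 / variances[term_index[t]] for t in col_meta])])
        joint = fitting.fit_poisson_strata(Xfull, y, strata, pen, fixed_stratum_variance, n_fixed)
        random_effects = {"stratum_intercept": {"variance": fixed_stratum_variance, "fixed": True}}
        for t in rs_terms:
            random_effects[f"animal_slope:{t}"] = {"variance": float(variances[term_index[t]]), "fixed": False}
    else:
        pen = np.zeros(n_fixed)
        joint = fitting.fit_poisson_strata(X, y, strata, pen, fixed_stratum_variance, n_fixed)
        random_effects = {"stratum_intercept": {"variance": fixed_stratum_variance, "fixed": True}}

    se = np.sqrt(np.clip(np.diag(joint.vcov_theta)[:n_fixed], 0.0, None))
    return ModelFit(
        terms=terms,
        estimates={t: float(joint.theta[i]) for i, t in enumerate(terms)},
        se={t: float(se[i]) for i, t in enumerate(terms)},
        loglik=float(joint.loglik_marginal),
        n_obs=len(data),
        converged=joint.converged,
        random_effects=random_effects,
        flags=list(joint.flags),
        extra={
            "model_name": name,
            "n_strata": int(len(np.unique(strata))),
            "vcov": joint.vcov_theta[:n_fixed, :n_fixed].tolist(),
            "loglik_data": joint.loglik_data,
        },
    )


def fit_clogit_exact(data: pd.DataFrame, model) -> ModelFit:
    """Exact conditional-logistic Newton fit (no random slopes): the oracle."""
    name, terms = _terms_of(model)
    X = term_matrix(data, terms)
    y = data["case"].to_numpy(dtype=float)
    strata = data["stratum_id"].to_numpy()
    beta, vcov, ll, converged, flags = fitting.fit_clogit_newton(X, y, strata)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    return ModelFit(
        terms=terms,
        estimates={t: float(beta[i]) for i, t in enumerate(terms)},
        se={t: float(se[i]) for i, t in enumerate(terms)},
        loglik=float(ll),
        n_obs=len(data),
        converged=converged,
        flags=list(flags),
        extra={"model_name": name, "vcov": vcov.tolist()},
    )


# ---------------------------------------------------------------------------
# Model and radius selection
# ---------------------------------------------------------------------------

def rank_by_aic(fits: dict) -> pd.DataFrame:
    """AIC table (ascending; ties broken by fewer parameters)."""
    rows = []
    for name, fit in fits.items():
        if not fit.converged:
            warnings.warn(f"excluding non-converged fit {name!r} from AIC ranking", stacklevel=2)
            continue
        rows.append({"model": name, "k": fit.n_params, "loglik": fit.loglik, "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def select_density_radius(
    data: pd.DataFrame,
    radii_km=(1.0, 3.0, 5.0),
    terms=None,
    **fit_kwargs,
):
    """Pick the boma-density radius by AIC over single SSFs (one per radius).

    ``data`` must carry ``dens_human_{r}km`` columns for every radius.
    Returns (chosen_radius, table); ties go to the smallest radius, and a
    radius whose fit fails is excluded with a warning.
    """
    radii_km = sorted(radii_km)
    fits = {}
    for r in radii_km:
        try:
            fits[r] = fit_ssf_poisson(with_density_radius(data, r), terms or DEFAULT_TERMS, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - a failed radius is excluded, not fatal
            warnings.warn(f"radius {r} km fit failed: {exc}", stacklevel=2)
    if not fits:
        raise RuntimeError("no radius produced a usable fit")
    rows = [{"radius_km": r, "k": f.n_params, "loglik": f.loglik, "aic": f.aic} for r, f in fits.items()]
    table = pd.DataFrame(rows).sort_values(["aic", "radius_km"], kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return float(table["radius_km"].iloc[0]), table
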