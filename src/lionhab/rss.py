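"""Relative selection strength (RSS) curves and resistance surfaces.

RSS compares the selection probability of a location whose covariate differs
from the landscape mean by Delta-h with that of an average location:
RSS(Delta-h) = exp(beta * Delta-h) for a scaled covariate (mean 0), using the
main-effect slope with any interaction partners held at their scaled mean.
Per-cell resistance is 1 - RSS accumulated over the model's covariates; a
linear approximation of each RSS curve (intercept alpha0, slope alpha_x from
least squares on a 200-point grid) is the default, with the exact exponential
form available as a mode.  Resistance can be negative (attraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ModelFit
from .landscape import CovariateStack
from .raster import RasterGrid

N_GRID = 200


@dataclass
class RSSCurve:
    covariate: str
    season: str
    layer: str
    grid: np.ndarray  # equally spaced scaled covariate values
    rss_values: np.ndarray
    beta: float
    alpha0: float  # intercept of the linear RSS fit
    alphax: float  # slope of the linear RSS fit


@dataclass
class ResistanceSurface:
    raster: RasterGrid
    display: RasterGrid  # signed-log transformed
    season: str
    mode: str
    provenance: dict = field(default_factory=dict)


def rss_curve(
    fit: ModelFit,
    covariate: str,
    stack: CovariateStack,
    season: str,
    n_grid: int = N_GRID,
    layer_name: str | None = None,
) -> RSSCurve:
    """RSS curve over ``n_grid`` equally spaced values of the covariate's
    scaled range, with the least-squares linear approximation stored.

    ``layer_name`` maps a model term to its stack layer when they differ
    (e.g. term ``dens_human`` backed by layer ``dens_human_3km``).
    """
    if covariate not in fit.terms:
        raise ValueError(f"covariate {covariate!r} not in the fitted model")
    if not fit.converged:
        raise ValueError("fit did not converge")
    layer_name = layer_name or covariate
    layer = stack.resolve(layer_name, season)
    vals = layer.values[~layer.is_nodata()]
    grid = np.linspace(float(vals.min()), float(vals.max()), n_grid)
    beta = fit.estimates[covariate]
    rss = np.exp(beta * grid)  # Delta-h = grid - 0 (scaled landscape mean)
    A = np.column_stack([np.ones(n_grid), grid])
    (alpha0, alphax), *_ = np.linalg.lstsq(A, rss, rcond=None)
    return RSSCurve(covariate, season, layer_name, grid, rss, float(beta), float(alpha0), float(alphax))


def resistance_surface(
    curves: list,
    stack: CovariateStack,
    season: str,
    mode: str = "linear_fit",
    provenance: dict | None = None,
) -> ResistanceSurface:
    """Sum per-covariate resistance (1 - RSS) over the stack's cells.

    ``linear_fit`` uses each curve's linear approximation
    R = sum_c [1 - (alpha0_c + alphax_c * X_c)]; ``exact_exp`` uses
    R = sum_c [1 - exp(beta_c * X_c)].
    """
    if mode not in ("linear_fit", "exact_exp"):
        raise ValueError(f"unknown mode {mode!r}")
    template = stack.template
    total = np.zeros_like(template.values)
    valid = np.ones(template.values.shape, dtype=bool)
    for curve in curves:
        layer = stack.resolve(curve.layer, season)
        if not layer.same_geometry(template):
            raise ValueError(f"layer {curve.covariate!r} geometry mismatch")
        x = layer.values
        mask = ~layer.is_nodata()
        valid &= mask
        if mode == "linear_fit":
            r = 1.0 - (curve.alpha0 + curve.alphax * x)
        else:
            r = 1.0 - np.exp(curve.beta * x)
        total += np.where(mask, r, 0.0)
    values = np.where(valid, total, template.nodata)
    raster = template.copy_with(values, season_tag=season)
    raster.nodata = template.nodata
    return ResistanceSurface(
        raster=raster,
        display=display_transform(raster),
        season=season,
        mode=mode,
        provenance=provenance or {},
    )


def display_transform(surface: RasterGrid) -> RasterGrid:
    """Signed-log display scale sign(R) * log(1 + |R|): odd, monotone, and
    defined for negative (attractive) resistance."""
    mask = surface.is_nodata()
    r = surface.values
    out = np.where(mask, surface.nodata, np.sign(r) * np.log1p(np.abs(r)))
    grid = surface.copy_with(out)
    return grid


def curves_to_json_dict(curves: list) -> dict:
    return {
        c.covariate: {
            "season": c.season,
            "beta": c.beta,
            "alpha0": c.alpha0,
            "alphax": c.alphax,
            "grid": c.grid.tolist(),
            "rss": c.rss_values.tolist(),
        }
        for c in curves
    }
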