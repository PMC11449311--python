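"""Used-habitat calibration (UHC) plots.

The data are split by stratum into training and testing halves; the model is
fitted on the training half.  Coefficient uncertainty is propagated by
sampling slope vectors from the multivariate normal of the estimates; for
each draw, "predicted used" points are resampled from the test available
points with weights exp(beta* ' x), and the covariate values are smoothed
into a density.  The pointwise 2.5/97.5 percentile band over draws is the
simulation envelope; a well-calibrated model keeps the observed test-used
density inside the envelope at most grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelFit, term_matrix

N_DRAWS = 1000
GRID_POINTS = 512


@dataclass
class UHCResult:
    covariates: list
    grid: dict  # covariate -> evaluation grid
    observed: dict  # covariate -> observed test-used density
    lower: dict
    upper: dict
    availability: dict
    coverage_fraction: dict  # covariate -> fraction of grid where observed in band
    n_draws: int = N_DRAWS
    meta: dict = field(default_factory=dict)


def uhc_split(data: pd.DataFrame, seed: int = 0):
    """Random stratum-level 50/50 split; half sizes differ by <= 1 stratum."""
    strata = data["stratum_id"].unique()
    if len(strata) < 2:
        raise ValueError("need >= 2 strata to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(strata)
    n_train = (len(strata) + 1) // 2
    train_ids = set(perm[:n_train])
    is_train = data["stratum_id"].isin(train_ids)
    return data[is_train].reset_index(drop=True), data[~is_train].reset_index(drop=True)


def _gauss_density(points: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (grid[:, None] - points[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(points) * bandwidth * np.sqrt(2 * np.pi))


def uhc_simulate(
    fit: ModelFit,
    test: pd.DataFrame,
    n_draws: int = N_DRAWS,
    seed: int = 0,
    grid_points: int = GRID_POINTS,
    covariates=None,
) -> UHCResult:
    """Simulation envelope of predicted used-habitat densities on test data.

    The kernel bandwidth (Gaussian, Scott's rule on the test used values) is
    held fixed across observed and simulated densities so that envelope
    coverage reflects model calibration, not smoothing differences.
    ``covariates`` selects the panels to evaluate; it defaults to the
    covariates appearing in the model, but may include covariates *omitted*
    from the model — their panels are exactly how a missing predictor is
    detected.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; UHC simulation undefined")
    vcov = np.asarray(fit.extra.get("vcov"))
    if vcov is None or not np.all(np.isfinite(vcov)):
        raise ValueError("fit carries no usable coefficient covariance")
    beta_terms = [t for t in fit.terms if t != "(Intercept)"]
    idx = [fit.terms.index(t) for t in beta_terms]
    beta_hat = np.array([fit.estimates[t] for t in beta_terms])
    V = vcov[np.ix_(idx, idx)]
    try:
        chol = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient covariance") from exc

    rng = np.random.default_rng(seed)
    test = test.sort_values(["stratum_id", "case"], ascending=[True, False]).reset_index(drop=True)
    used = test[test["case"] == 1]
    avail = test[test["case"] == 0]
    n_used = len(used)
    # predicted used points are drawn within strata (one per stratum), matching
    # the conditional structure of the step-selection likelihood
    counts = avail.groupby("stratum_id", sort=True).size()
    if counts.nunique() != 1:
        raise ValueError("every test stratum must have the same number of available points")
    K = int(counts.iloc[0])
    S = len(counts)
    X_avail = term_matrix(avail, beta_terms).reshape(S, K, len(beta_terms))
    if covariates is None:
        covariates = sorted({p for t in beta_terms for p in t.split(":")})
    covariates = list(covariates)

    grids, observed, lower, upper, availability, coverage = {}, {}, {}, {}, {}, {}
    avail_cols = {c: avail[c].to_numpy(dtype=float).reshape(S, K) for c in covariates}
    used_cols = {c: used[c].to_numpy(dtype=float) for c in covariates}
    bandwidths, dens_draws = {}, {}
    for c in covariates:
        lo, hi = avail_cols[c].min(), avail_cols[c].max()
        pad = 0.05 * (hi - lo + 1e-12)
        grids[c] = np.linspace(lo - pad, hi + pad, grid_points)
        # Scott's rule with the spread taken from the pooled test values (used
        # and available): the common bandwidth keeps observed and simulated
        # densities comparable and smooths over the K-point availability support
        sd = np.concatenate([used_cols[c], avail_cols[c].ravel()]).std(ddof=1)
        bandwidths[c] = max(sd, 1e-6) * n_used ** (-1.0 / 5.0)
        observed[c] = _gauss_density(used_cols[c], grids[c], bandwidths[c])
        availability[c] = _gauss_density(avail_cols[c].ravel(), grids[c], bandwidths[c])
        dens_draws[c] = np.empty((n_draws, grid_points))

    rows = np.arange(S)
    for d in range(n_draws):
        beta_star = beta_hat + chol @ rng.standard_normal(len(beta_hat))
        lp = X_avail @ beta_star  # (S, K)
        # Gumbel-max trick: one categorical draw per stratum, prob ~ exp(lp)
        pick = np.argmax(lp + rng.gumbel(size=(S, K)), axis=1)
        for c in covariates:
            dens_draws[c][d] = _gauss_density(avail_cols[c][rows, pick], grids[c], bandwidths[c])

    for c in covariates:
        lower[c] = np.percentile(dens_draws[c], 2.5, axis=0)
        upper[c] = np.percentile(dens_draws[c], 97.5, axis=0)
        inside = (observed[c] >= lower[c]) & (observed[c] <= upper[c])
        coverage[c] = float(inside.mean())

    return UHCResult(
        covariates=covariates,
        grid=grids,
        observed=observed,
        lower=lower,
        upper=upper,
        availability=availability,
        coverage_fraction=coverage,
        n_draws=n_draws,
        meta={"n_used_test": n_used, "n_avail_test": len(avail), "seed": seed},
    )


def uhc_result_frames(result: UHCResult) -> dict:
    """Per-covariate DataFrames (grid, observed, lower, upper, availability)."""
    return {
        c: pd.DataFrame(
            {
                "grid": result.grid[c],
                "observed": result.observed[c],
                "lower": result.lower[c],
                "upper": result.upper[c],
                "availability": result.availability[c],
            }
        )
        for c in result.covariates
    }


def uhc_plot(result: UHCResult, path=None):
    """One panel per covariate: observed (solid), envelope (band),
    availability (dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.covariates)
    ncols = min(n, 3)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, c in zip(axes.ravel(), result.covariates):
        ax.fill_between(result.grid[c], result.lower[c], result.upper[c], color="0.8", label="95% envelope")
        ax.plot(result.grid[c], result.observed[c], "k-", label="observed used")
        ax.plot(result.grid[c], result.availability[c], "r--", label="available")
        ax.set_title(f"{c} (coverage {result.coverage_fraction[c]:.2f})")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
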