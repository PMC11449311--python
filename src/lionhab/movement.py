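"""Synthetic lion tracks from a known step-selection generative model.

Each simulated step draws candidate endpoints from a movement kernel (gamma
step lengths, von Mises turn angles) and selects one with probability
proportional to exp(beta' x) evaluated on the scaled landscape covariates.
Because the true coefficients are known, every downstream estimator (kernel
fitting, SSF, RSF, radius selection, calibration) can be validated by
parameter recovery on these tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import base_covariates, term_matrix
from .landscape import CovariateStack, extract_matrix, place_bomas_seasonal  # noqa: F401
from .trajectory import MovementKernel, season_of, wrap_angle

#: candidate endpoints per simulated step (distinct from the analysis' 50
#: available steps) so the exponential weighting is well approximated; with
#: only ~200 candidates the discrete choice measurably attenuates recovered
#: slopes once the chain settles into high-selection patches
N_CANDIDATES = 1000

MIN_STEP_M = 1.0  # floor avoids degenerate turn angles at zero-length steps


@dataclass
class SelectionCoefficients:
    """True selection coefficients on the scaled-covariate scale.

    ``beta`` maps terms (covariate names, or interactions like
    ``"cover:dist_human"``) to slopes; ``individual_offsets`` maps an animal
    id to per-term coefficient deviations.
    """

    beta: dict
    individual_offsets: dict = field(default_factory=dict)

    def for_animal(self, animal_id) -> dict:
        off = self.individual_offsets.get(animal_id, {})
        return {t: self.beta[t] + off.get(t, 0.0) for t in self.beta}


def _lp_upper_bound(stack: CovariateStack, beta: dict) -> dict:
    """Per-season upper bound on beta'x over the landscape (for rejection
    sampling).  Interaction terms are bounded by the extreme products of
    their partners' layer ranges."""
    bounds = {}
    for season in ("wet", "dry"):
        total = 0.0
        for term, b in beta.items():
            if b == 0.0:
                continue
            extremes = []
            for part in term.split(":"):
                layer = stack.resolve(part, season)
                vals = layer.values[~layer.is_nodata()]
                extremes.append((float(vals.min()), float(vals.max())))
            if len(extremes) == 1:
                lo, hi = extremes[0]
                prods = [lo, hi]
            else:
                prods = [a * c for a in extremes[0] for c in extremes[1]]
            total += max(b * p for p in prods)
        bounds[season] = total
    return bounds


def _draw_candidates(rng, kernel: MovementKernel, heading: float, n: int):
    lengths = np.maximum(rng.gamma(kernel.gamma_shape, kernel.gamma_scale, n), MIN_STEP_M)
    if np.isfinite(heading):
        if kernel.vm_kappa > 0:
            turns = rng.vonmises(kernel.vm_mu, kernel.vm_kappa, n)
        else:
            turns = rng.uniform(-np.pi, np.pi, n)
        angles = wrap_angle(heading + turns)
    else:
        angles = rng.uniform(-np.pi, np.pi, n)  # no previous heading at step 1
    return lengths, angles


def simulate_ssf_track(
    stack: CovariateStack,
    kernel: MovementKernel,
    coeffs: SelectionCoefficients,
    start: tuple,
    n_steps: int,
    fix_interval_hours: float = 1.0,
    seed: int = 0,
    animal_id: str = "sim",
    start_time="2023-01-01T00:00:00Z",
    n_candidates: int = N_CANDIDATES,
    max_redraw_rounds: int = 200,
    method: str = "rejection",
) -> pd.DataFrame:
    """Simulate one track by repeated kernel-and-selection steps.

    ``stack`` must be scaled (the coefficients act on scaled covariates).
    Candidates leaving the extent or landing on nodata are redrawn; seasonal
    layers switch with the calendar month of the arrival time.

    ``method="rejection"`` (default) draws each step exactly from the target
    density kernel(s) * exp(beta'x(s)) by rejection sampling against a global
    upper bound on the linear predictor; ``method="softmax"`` instead selects
    among ``n_candidates`` kernel draws with probability proportional to
    exp(beta'x), which is approximate (slopes recovered from long tracks are
    attenuated when the candidate count is small).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not stack.scaling:
        raise ValueError("stack must be scaled before simulation")
    rng = np.random.default_rng(seed)
    template = stack.template
    x, y = float(start[0]), float(start[1])
    if not template.contains(x, y):
        raise ValueError("start position outside the landscape extent")
    beta = coeffs.for_animal(animal_id)
    terms = list(beta)
    bases = base_covariates(terms)
    if np.isnan(extract_matrix(stack, [x], [y], [season_of(pd.Timestamp(start_time))], bases)).any():
        raise ValueError("start position lies on nodata")
    t0 = pd.Timestamp(start_time)
    times = [t0]
    xs, ys = [x], [y]
    heading = np.nan
    bvec = np.array([beta[t] for t in terms])
    lp_bound = _lp_upper_bound(stack, beta) if method == "rejection" else None

    def candidate_pool(n, season):
        """In-extent, non-nodata kernel draws with their linear predictors."""
        lengths, angles = _draw_candidates(rng, kernel, heading, n)
        px = x + lengths * np.cos(angles)
        py = y + lengths * np.sin(angles)
        ok = template.contains(px, py)
        if not ok.any():
            return px[:0], py[:0], np.empty(0)
        vals = extract_matrix(stack, px[ok], py[ok], np.full(int(ok.sum()), season), bases)
        good = ~np.isnan(vals).any(axis=1)
        covs = {b: vals[good, j] for j, b in enumerate(bases)}
        lp = term_matrix(covs, terms) @ bvec
        return px[ok][good], py[ok][good], lp

    for step in range(n_steps):
        t_end = t0 + pd.Timedelta(hours=fix_interval_hours * (step + 1))
        season = season_of(t_end)
        chosen = None
        if method == "rejection":
            for _ in range(max_redraw_rounds):
                px, py, lp = candidate_pool(512, season)
                if not len(px):
                    continue
                accept = np.log(rng.uniform(size=len(px))) < lp - lp_bound[season]
                hits = np.where(accept)[0]
                if len(hits):
                    chosen = (px[hits[0]], py[hits[0]])
                    break
            if chosen is None:
                raise RuntimeError("rejection sampling failed; selection surface too extreme?")
        else:
            cx, cy, clp = np.empty(0), np.empty(0), np.empty(0)
            for _ in range(max_redraw_rounds):
                if len(cx) >= n_candidates:
                    break
                px, py, lp = candidate_pool(2 * (n_candidates - len(cx)), season)
                cx, cy, clp = np.concatenate([cx, px]), np.concatenate([cy, py]), np.concatenate([clp, lp])
            else:
                raise RuntimeError("could not draw in-extent candidates; start too close to a boundary?")
            cx, cy, clp = cx[:n_candidates], cy[:n_candidates], clp[:n_candidates]
            w = np.exp(clp - clp.max())
            idx = rng.choice(len(cx), p=w / w.sum())
            chosen = (cx[idx], cy[idx])
        heading = float(np.arctan2(chosen[1] - y, chosen[0] - x))
        x, y = float(chosen[0]), float(chosen[1])
        xs.append(x)
        ys.append(y)
        times.append(t_end)
    return pd.DataFrame(
        {"animal_id": animal_id, "timestamp": pd.DatetimeIndex(times, tz="UTC"), "x": xs, "y": ys}
    )


def simulate_home_range_track(
    center: tuple,
    attraction: float,
    kernel: MovementKernel,
    n_steps: int,
    seed: int = 0,
    animal_id: str = "sim",
    start_time="2023-01-01T00:00:00Z",
    fix_interval_hours: float = 1.0,
) -> pd.DataFrame:
    """Biased random walk whose heading is pulled toward a home-range center.

    ``attraction`` in (0, 1] weights the pull: near 0 the walk is unbiased
    (MSD grows ~linearly), at 1 with a vanishing kernel scale the animal sits
    at the center.
    """
    if not (0.0 < attraction <= 1.0):
        raise ValueError("attraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    x, y = float(center[0]), float(center[1])
    heading = rng.uniform(-np.pi, np.pi)
    t0 = pd.Timestamp(start_time)
    xs, ys, times = [x], [y], [t0]
    for step in range(n_steps):
        lengths, angles = _draw_candidates(rng, kernel, heading, 1)
        base = angles[0]
        dx, dy = center[0] - x, center[1] - y
        if np.hypot(dx, dy) > 1e-9:
            pull = np.arctan2(dy, dx)
            vx = (1 - attraction) * np.cos(base) + attraction * np.cos(pull)
            vy = (1 - attraction) * np.sin(base) + attraction * np.sin(pull)
            heading = float(np.arctan2(vy, vx)) if (abs(vx) + abs(vy)) > 1e-12 else base
        else:
            heading = base
        length = min(lengths[0], np.hypot(dx, dy)) if attraction >= 1.0 and np.hypot(dx, dy) > 0 else lengths[0]
        x += length * np.cos(heading)
        y += length * np.sin(heading)
        xs.append(x)
        ys.append(y)
        times.append(t0 + pd.Timedelta(hours=fix_interval_hours * (step + 1)))
    return pd.DataFrame(
        {"animal_id": animal_id, "timestamp": pd.DatetimeIndex(times, tz="UTC"), "x": xs, "y": ys}
    )
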