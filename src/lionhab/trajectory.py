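"""GPS-track preparation: resampling, season/diel annotation, step building,
movement-kernel fitting, and mean squared displacement.

A track is a pandas DataFrame with columns ``animal_id``, ``timestamp``
(tz-aware UTC), ``x``, ``y`` (projected meters), time-sorted within animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import special, stats

from . import solar

TRACK_COLUMNS = ["animal_id", "timestamp", "x", "y"]

#: months of the wet season (rains: short rains Nov-Dec, long rains Mar-Apr;
#: pasture response gives good wet-season grazing Dec-May)
WET_MONTHS = (12, 1, 2, 3, 4, 5)

MIN_KERNEL_STEPS = 30
KAPPA_CAP = 700.0


@dataclass
class MovementKernel:
    """Parametric movement kernel: gamma step lengths, von Mises turn angles."""

    gamma_shape: float
    gamma_scale: float  # meters
    vm_mu: float  # radians in (-pi, pi]
    vm_kappa: float
    degenerate: bool = False  # kappa hit its cap

    def __post_init__(self) -> None:
        if not (self.gamma_shape > 0 and self.gamma_scale > 0):
            raise ValueError("gamma shape and scale must be > 0")
        if self.vm_kappa < 0:
            raise ValueError("vm_kappa must be >= 0")


def wrap_angle(a):
    """Wrap to (-pi, pi]; exact reversals map to +pi by convention."""
    a = np.asarray(a, dtype=float)
    out = np.remainder(a + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


# ---------------------------------------------------------------------------
# Cleaning and annotation
# ---------------------------------------------------------------------------

def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    for col in TRACK_COLUMNS:
        if col not in track.columns:
            raise ValueError(f"track missing column {col!r}")
    return track


def resample_track(track: pd.DataFrame, interval_hours: float = 12.0, tolerance_minutes: float = 120.0) -> pd.DataFrame:
    """Greedy thinning to ~``interval_hours`` spacing (per animal).

    Keeps the first fix, then repeatedly the fix closest to one interval
    after the last kept fix among those within +-tolerance; across data gaps
    (no fix in the window) it resumes at the next fix beyond the window.
    Idempotent.
    """
    _check_track(track)
    if track.empty:
        return track.copy()
    target = pd.Timedelta(hours=interval_hours)
    tol = pd.Timedelta(minutes=tolerance_minutes)
    kept = []
    for _, sub in track.groupby("animal_id", sort=False):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        times = sub["timestamp"]
        keep = [0]
        i = 1
        while i < len(sub):
            dt = times - times[keep[-1]]
            window = np.where((dt >= target - tol) & (dt <= target + tol))[0]
            window = window[window >= i]
            if len(window):
                best = window[np.argmin(np.abs((dt.iloc[window] - target).to_numpy()))]
            else:
                beyond = np.where(dt > target + tol)[0]
                beyond = beyond[beyond >= i]
                if not len(beyond):
                    break
                best = beyond[0]
            keep.append(int(best))
            i = best + 1
        kept.append(sub.iloc[keep])
    return pd.concat(kept, ignore_index=True)


def annotate_season(track: pd.DataFrame) -> pd.DataFrame:
    """Label each fix wet (Dec-May) or dry (Jun-Nov) by calendar month."""
    out = track.copy()
    months = pd.DatetimeIndex(out["timestamp"]).month
    out["season"] = np.where(np.isin(months, WET_MONTHS), "wet", "dry")
    return out


def season_of(ts) -> str:
    month = pd.Timestamp(ts).month
    return "wet" if month in WET_MONTHS else "dry"


def annotate_diel(track: pd.DataFrame, ref_lon: float, ref_lat: float, ref_x: float = 0.0, ref_y: float = 0.0) -> pd.DataFrame:
    """Label each fix day/night from the solar elevation at its time and place."""
    out = track.copy()
    lon, lat = solar.xy_to_lonlat(out["x"].to_numpy(), out["y"].to_numpy(), ref_lon, ref_lat, ref_x, ref_y)
    ts = out["timestamp"].to_numpy()
    day = np.empty(len(out), dtype=bool)
    # elevation depends on each fix's lon/lat; loop is fine at telemetry sizes
    for i in range(len(out)):
        day[i] = bool(solar.is_day(ts[i], float(np.atleast_1d(lon)[i]), float(np.atleast_1d(lat)[i]))[0])
    out["diel"] = np.where(day, "day", "night")
    return out


def clip_to_study_area(track: pd.DataFrame, polygon) -> pd.DataFrame:
    """Drop fixes outside the study-area polygon (landscape-scale analysis only)."""
    _check_track(track)
    if track.empty:
        return track.copy()
    pts = shapely.points(np.column_stack([track["x"].to_numpy(), track["y"].to_numpy()]))
    inside = shapely.contains(polygon, pts)
    if not inside.any():
        import warnings

        warnings.warn("all fixes fall outside the study area", stacklevel=2)
    return track[inside].reset_index(drop=True)


def assign_category(track: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach the life-stage category (female / resident_male / nomadic_male)
    active at each fix's timestamp; fixes outside any interval get NaN.

    ``intervals`` columns: animal_id, category, start, end (UTC).
    """
    out = track.copy()
    out["category"] = pd.Series(pd.NA, index=out.index, dtype="object")
    for _, iv in intervals.iterrows():
        m = (
            (out["animal_id"] == iv["animal_id"])
            & (out["timestamp"] >= iv["start"])
            & (out["timestamp"] < iv["end"])
        )
        out.loc[m, "category"] = iv["category"]
    return out


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def build_steps(track: pd.DataFrame, step_interval_hours: float = 1.0, tolerance_minutes: float = 30.0) -> pd.DataFrame:
    """Consecutive fix pairs at the target interval become used steps.

    Bursts break at data gaps; the turn angle (signed heading change in
    (-pi, pi], reversal = +pi) is defined only when the preceding step is in
    the same burst.  Columns include start/end coordinates and times, heading,
    step_length (m), turn_angle (NaN at burst starts).
    """
    _check_track(track)
    lo = pd.Timedelta(hours=step_interval_hours) - pd.Timedelta(minutes=tolerance_minutes)
    hi = pd.Timedelta(hours=step_interval_hours) + pd.Timedelta(minutes=tolerance_minutes)
    rows = []
    for animal, sub in track.groupby("animal_id", sort=False):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        prev_heading = np.nan
        prev_end_idx = -2
        for i in range(len(sub) - 1):
            dt = sub["timestamp"][i + 1] - sub["timestamp"][i]
            if not (lo <= dt <= hi):
                prev_heading = np.nan
                continue
            dx = sub["x"][i + 1] - sub["x"][i]
            dy = sub["y"][i + 1] - sub["y"][i]
            heading = float(np.arctan2(dy, dx))
            contiguous = i == prev_end_idx
            turn = float(wrap_angle(heading - prev_heading)) if (contiguous and np.isfinite(prev_heading)) else np.nan
            rows.append(
                {
                    "animal_id": animal,
                    "t_start": sub["timestamp"][i],
                    "t_end": sub["timestamp"][i + 1],
                    "x_start": sub["x"][i],
                    "y_start": sub["y"][i],
                    "x_end": sub["x"][i + 1],
                    "y_end": sub["y"][i + 1],
                    "step_length": float(np.hypot(dx, dy)),
                    "heading": heading,
                    "turn_angle": turn,
                }
            )
            prev_heading = heading
            prev_end_idx = i + 1
    steps = pd.DataFrame(rows)
    if not steps.empty:
        steps["stratum_id"] = [f"{a}_{i}" for i, a in enumerate(steps["animal_id"])]
    return steps


def fit_movement_kernel(steps: pd.DataFrame, min_steps: int = MIN_KERNEL_STEPS) -> MovementKernel:
    """Maximum-likelihood gamma (step length) and von Mises (turn angle) fits."""
    lengths = steps["step_length"].to_numpy(dtype=float)
    angles = steps["turn_angle"].to_numpy(dtype=float)
    angles = angles[np.isfinite(angles)]
    if len(angles) < min_steps:
        raise ValueError(f"need >= {min_steps} steps with defined turn angles, got {len(angles)}")
    lengths = lengths[lengths > 0]
    if np.ptp(lengths) == 0:
        raise ValueError("all step lengths identical; gamma fit is degenerate")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    mu, kappa, degenerate = _vonmises_mle(angles)
    return MovementKernel(float(shape), float(scale), float(mu), float(kappa), degenerate)


def _vonmises_mle(angles: np.ndarray):
    """Closed-form mu; kappa by Newton inversion of A1(kappa) = Rbar."""
    s, c = np.sin(angles).mean(), np.cos(angles).mean()
    mu = float(np.arctan2(s, c))
    rbar = float(np.hypot(s, c))
    if rbar < 1e-12:
        return mu, 0.0, False
    if rbar >= 1.0 - 1e-12:
        return mu, KAPPA_CAP, True
    # Banerjee et al. starting value, then Newton on A1(k) - rbar
    k = rbar * (2.0 - rbar**2) / (1.0 - rbar**2)
    for _ in range(50):
        a1 = special.i1e(k) / special.i0e(k)
        # d A1/dk = 1 - A1/k - A1^2
        deriv = 1.0 - a1 / k - a1 * a1 if k > 0 else 0.5
        step = (a1 - rbar) / deriv
        k = max(k - step, 1e-8)
        if abs(step) < 1e-10:
            break
    if k >= KAPPA_CAP:
        return mu, KAPPA_CAP, True
    return mu, float(k), False


# ---------------------------------------------------------------------------
# Mean squared displacement
# ---------------------------------------------------------------------------

def mean_squared_displacement(track: pd.DataFrame) -> float:
    """MSD in km^2 relative to the first fix of the (filtered) track."""
    if len(track) < 2:
        raise ValueError("MSD needs at least 2 fixes")
    sub = track.sort_values("timestamp")
    x = sub["x"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    d2 = (x - x[0]) ** 2 + (y - y[0]) ** 2
    return float(d2.mean() / 1e6)


def msd_table(track: pd.DataFrame, by=("animal_id", "season")) -> pd.DataFrame:
    """Per animal-season MSD (km^2) and its square root (km)."""
    if "season" not in track.columns:
        track = annotate_season(track)
    rows = []
    for keys, sub in track.groupby(list(by)):
        if len(sub) < 2:
            continue
        msd = mean_squared_displacement(sub)
        rows.append(dict(zip(by, keys if isinstance(keys, tuple) else (keys,))) | {"msd_km2": msd, "rmsd_km": np.sqrt(msd)})
    return pd.DataFrame(rows)


def msd_season_model(table: pd.DataFrame, response: str = "msd_km2"):
    """Gamma GLM (log link) of MSD on season, dry season as reference.

    Returns a dict with the wet-vs-dry coefficient, its SE, 95% CI, and the
    implied wet/dry MSD ratio exp(coefficient).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if (table[response] <= 0).any():
        raise ValueError("MSD values must be positive for a Gamma GLM")
    both = table.groupby("animal_id")["season"].nunique()
    if (both >= 2).sum() < 2:
        raise ValueError("need >= 2 animals observed in both seasons")
    means = table.groupby("season")[response].agg(["mean", "var"])
    if (means["var"].fillna(0.0) < 1e-12 * means["mean"] ** 2).all():
        # perfectly constant response per season: the GLM scale is degenerate,
        # but the season effect is the log mean ratio in closed form
        coef = float(np.log(means.loc["wet", "mean"] / means.loc["dry", "mean"]))
        return {
            "coef_wet_vs_dry": coef,
            "se": 0.0,
            "ci95": (coef, coef),
            "ratio_wet_dry": float(np.exp(coef)),
            "intercept": float(np.log(means.loc["dry", "mean"])),
            "n": int(len(table)),
        }
    model = smf.glm(
        f"{response} ~ C(season, Treatment(reference='dry'))",
        data=table,
        family=sm.families.Gamma(link=sm.families.links.Log()),
    )
    res = model.fit()
    term = [t for t in res.params.index if "season" in t][0]
    coef = float(res.params[term])
    se = float(res.bse[term])
    return {
        "coef_wet_vs_dry": coef,
        "se": se,
        "ci95": (coef - 1.959964 * se, coef + 1.959964 * se),
        "ratio_wet_dry": float(np.exp(coef)),
        "intercept": float(res.params["Intercept"]),
        "n": int(res.nobs),
    }


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def read_track_csv(path) -> pd.DataFrame:
    track = pd.read_csv(path, parse_dates=["timestamp"])
    track["timestamp"] = pd.to_datetime(track["timestamp"], utc=True)
    return _check_track(track)


def write_track_csv(track: pd.DataFrame, path) -> None:
    out = track.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_intervals_csv(path) -> pd.DataFrame:
    iv = pd.read_csv(path)
    for col in ("start", "end"):
        iv[col] = pd.to_datetime(iv[col], utc=True)
    return iv
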