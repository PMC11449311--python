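"""Solar position for day/night classification of GPS fixes.

Implements the NOAA solar calculator equations (Julian-century polynomial
ephemeris for the sun, equation of time, declination, hour angle).  A fix is
classified as *day* when the solar elevation at its time and location exceeds
-0.833 degrees, the refraction-corrected sunrise/sunset horizon used by
standard solar calculators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: refraction-corrected horizon altitude (degrees) for the day/night boundary
HORIZON_DEG = -0.833


def _julian_day(ts) -> np.ndarray:
    """UTC timestamps -> Julian day (float)."""
    ts = pd.to_datetime(np.atleast_1d(ts), utc=True)
    unix = ts.asi8 / 1e9
    return unix / 86400.0 + 2440587.5


def solar_position(ts, lon: float, lat: float):
    """Solar elevation and azimuth (degrees) at UTC time(s) ``ts``.

    Longitude positive east, latitude positive north.  Elevation is geometric
    (no refraction term); the day/night rule compensates with HORIZON_DEG.
    """
    jd = _julian_day(ts)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000
    # geometric mean longitude / anomaly of the sun (deg)
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = np.radians(m)
    # equation of center, true longitude, apparent longitude
    c = (
        np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))
    # obliquity (corrected) and declination
    e0 = 23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = e0 + 0.00256 * np.cos(np.radians(omega))
    decl = np.degrees(np.arcsin(np.sin(np.radians(eps)) * np.sin(np.radians(app_long))))
    # equation of time (minutes)
    y = np.tan(np.radians(eps / 2.0)) ** 2
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mr)
        + 4.0 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * mr)
    )
    # true solar time -> hour angle
    frac_day = np.mod(jd + 0.5, 1.0)  # fraction of UTC day from midnight
    tst = np.mod(frac_day * 1440.0 + eot + 4.0 * lon, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)
    latr, declr, har = np.radians(lat), np.radians(decl), np.radians(ha)
    cos_zen = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(har)
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    elev = 90.0 - zen
    az = np.degrees(
        np.arccos(
            np.clip(
                (np.sin(latr) * np.cos(np.radians(zen)) - np.sin(declr))
                / (np.cos(latr) * np.sin(np.radians(zen))),
                -1.0,
                1.0,
            )
        )
    )
    az = np.where(ha > 0, np.mod(az + 180.0, 360.0), np.mod(540.0 - az, 360.0))
    return elev, az


def solar_elevation(ts, lon: float, lat: float):
    return solar_position(ts, lon, lat)[0]


def is_day(ts, lon: float, lat: float) -> np.ndarray:
    """True where the sun is above the refraction-corrected horizon."""
    return solar_elevation(ts, lon, lat) > HORIZON_DEG


def xy_to_lonlat(x, y, ref_lon: float, ref_lat: float, ref_x: float = 0.0, ref_y: float = 0.0):
    """Local equirectangular conversion of projected meters to lon/lat.

    Adequate for solar geometry over a study area of tens of km; not a CRS
    transform.
    """
    m_per_deg_lat = 110_574.0
    m_per_deg_lon = 111_320.0 * np.cos(np.radians(ref_lat))
    lon = ref_lon + (np.asarray(x, dtype=float) - ref_x) / m_per_deg_lon
    lat = ref_lat + (np.asarray(y, dtype=float) - ref_y) / m_per_deg_lat
    return lon, lat
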