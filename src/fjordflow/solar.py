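"""NOAA solar-position calculation for day/night classification.

Standard NOAA Solar Calculator formulas (fractional year, equation of time,
solar declination, hour angle -> elevation).  Accuracy is a few minutes
around sunrise/sunset, ample for classifying detections as day or night;
polar day/night simply yields elevations that never cross zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation(timestamps_utc, lat: float, lon: float) -> np.ndarray:
    """Solar elevation angle in degrees for tz-aware UTC timestamps."""
    ts = pd.DatetimeIndex(timestamps_utc)
    if ts.tz is None:
        raise ValueError("timestamps must be timezone-aware")
    ts = ts.tz_convert("UTC")

    doy = ts.dayofyear.to_numpy().astype(float)
    hour = (
        ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0 + ts.second.to_numpy() / 3600.0
    ).astype(float)
    leap = np.asarray(ts.is_leap_year)
    days_in_year = np.where(leap, 366.0, 365.0)

    # fractional year (radians)
    gamma = 2.0 * np.pi / days_in_year * (doy - 1.0 + (hour - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )

    time_offset = eqtime + 4.0 * lon  # minutes
    tst = hour * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle

    lat_r = np.deg2rad(lat)
    cos_zenith = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    zenith = np.arccos(np.clip(cos_zenith, -1.0, 1.0))
    return 90.0 - np.rad2deg(zenith)


def classify_daynight(timestamps_utc, lat: float, lon: float) -> np.ndarray:
    """'day' where solar elevation > 0, else 'night'."""
    elev = solar_elevation(timestamps_utc, lat, lon)
    return np.where(elev > 0.0, "day", "night")
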