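"""Apparent solar elevation (NOAA solar-position algorithm).

Implements the low-precision ephemeris used by the NOAA solar calculator
(Meeus-style truncated series), including the standard atmospheric
refraction correction.  Accuracy is well within a few hundredths of a
degree for the decades around J2000 — far tighter than the civil-twilight
classification (elevation > -6 deg) this pipeline needs it for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _to_julian_day(ts: np.ndarray) -> np.ndarray:
    # datetime64 UTC -> Julian day; unix epoch is JD 2440587.5
    secs = ts.astype("datetime64[ns]").astype("int64") / 1e9
    return secs / 86400.0 + 2440587.5


def solar_elevation(timestamps, lon, lat) -> np.ndarray:
    """Apparent solar elevation in degrees at UTC instants and positions.

    Parameters are scalars or broadcastable arrays; ``timestamps`` is
    anything ``pandas.to_datetime`` accepts (naive = UTC).
    """
    ts = pd.to_datetime(np.atleast_1d(np.asarray(timestamps))).to_numpy()
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    jd = _to_julian_day(ts)
    jc = (jd - 2451545.0) / 36525.0

    gml = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    gma_r = np.radians(gma)
    eq_ctr = (np.sin(gma_r) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
              + np.sin(2 * gma_r) * (0.019993 - 0.000101 * jc)
              + np.sin(3 * gma_r) * 0.000289)
    true_long = gml + eq_ctr
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(125.04 - 1934.136 * jc))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))

    decl = np.degrees(np.arcsin(np.sin(np.radians(obliq)) * np.sin(np.radians(app_long))))

    var_y = np.tan(np.radians(obliq / 2.0)) ** 2
    gml_r = np.radians(gml)
    eq_time_min = 4.0 * np.degrees(
        var_y * np.sin(2 * gml_r)
        - 2.0 * ecc * np.sin(gma_r)
        + 4.0 * ecc * var_y * np.sin(gma_r) * np.cos(2 * gml_r)
        - 0.5 * var_y ** 2 * np.sin(4 * gml_r)
        - 1.25 * ecc ** 2 * np.sin(2 * gma_r)
    )

    minutes_utc = (jd + 0.5 - np.floor(jd + 0.5)) * 1440.0
    tst = (minutes_utc + eq_time_min + 4.0 * lon) % 1440.0
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)

    lat_r = np.radians(lat)
    decl_r = np.radians(decl)
    cos_zen = (np.sin(lat_r) * np.sin(decl_r)
               + np.cos(lat_r) * np.cos(decl_r) * np.cos(np.radians(ha)))
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    elev = 90.0 - zen

    out = elev + _refraction_deg(elev)
    if np.isscalar(timestamps) or (np.ndim(timestamps) == 0 and out.size == 1):
        return float(out[0]) if out.ndim else float(out)
    return out


def _refraction_deg(elev: np.ndarray) -> np.ndarray:
    """NOAA atmospheric refraction correction (degrees) vs true elevation."""
    elev = np.asarray(elev, dtype=float)
    e_r = np.radians(np.clip(elev, -89.9, 89.9))
    tan_e = np.tan(e_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        high = 58.1 / tan_e - 0.07 / tan_e ** 3 + 0.000086 / tan_e ** 5
        low = -20.772 / tan_e
    mid = 1735.0 + elev * (-518.2 + elev * (103.4 + elev * (-12.79 + elev * 0.711)))
    corr = np.where(elev > 85.0, 0.0,
                    np.where(elev > 5.0, high,
                             np.where(elev > -0.575, mid, low)))
    return corr / 3600.0


def is_daylight(timestamps, lon, lat, elev_threshold_deg: float = -6.0) -> np.ndarray:
    """Daylight flag: apparent solar elevation strictly above threshold."""
    return np.asarray(solar_elevation(timestamps, lon, lat)) > elev_threshold_deg
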