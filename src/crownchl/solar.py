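"""Solar position from time and location.

Implements the NOAA solar-calculator algorithm (Meeus-based series for the
solar coordinates plus the equation of time).  Accuracy is a few hundredths
of a degree for years 1900-2100, far inside the 0.5 deg contract; atmospheric
refraction is not applied (irrelevant at the solar elevations simulated
here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

__all__ = ["SolarGeometry", "sun_position", "NightError"]


class NightError(ValueError):
    """Raised when an operation requires the sun above the horizon."""


@dataclass(frozen=True)
class SolarGeometry:
    """Sun direction for one time and place.

    Attributes
    ----------
    zenith : float
        Solar zenith angle, degrees (>= 90 means sun at/below horizon).
    azimuth : float
        Solar azimuth, degrees clockwise from north in [0, 360).
    night : bool
        True when the geometric zenith is >= 90 degrees.
    """

    local_datetime: datetime
    latitude: float
    longitude: float
    zenith: float
    azimuth: float

    @property
    def night(self) -> bool:
        return self.zenith >= 90.0

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith

    def require_daytime(self) -> "SolarGeometry":
        if self.night:
            raise NightError(
                f"sun below horizon at {self.local_datetime.isoformat()} "
                f"(zenith {self.zenith:.2f} deg)"
            )
        return self


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = (
        dt_utc.day
        + (dt_utc.hour + dt_utc.minute / 60.0 + dt_utc.second / 3600.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def sun_position(latitude: float, longitude: float, when: datetime) -> SolarGeometry:
    """Compute solar zenith/azimuth for a timezone-aware timestamp.

    Parameters
    ----------
    latitude, longitude : float
        Degrees; east longitude positive.
    when : datetime
        Must carry tzinfo (the UTC offset defines local time).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude out of range: {latitude}")
    if not -180.0 <= longitude <= 360.0:
        raise ValueError(f"longitude out of range: {longitude}")
    if when.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")

    dt_utc = when.astimezone(timezone.utc)
    jd = _julian_day(dt_utc)
    t = (jd - 2451545.0) / 36525.0

    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    obliq_rad = math.radians(obliq)
    app_long_rad = math.radians(app_long)

    decl = math.asin(math.sin(obliq_rad) * math.sin(app_long_rad))

    var_y = math.tan(obliq_rad / 2.0) ** 2
    l0rad = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0rad)
        - 2.0 * ecc * math.sin(mrad)
        + 4.0 * ecc * var_y * math.sin(mrad) * math.cos(2 * l0rad)
        - 0.5 * var_y**2 * math.sin(4 * l0rad)
        - 1.25 * ecc**2 * math.sin(2 * mrad)
    )

    minutes_utc = dt_utc.hour * 60.0 + dt_utc.minute + dt_utc.second / 60.0
    tst = (minutes_utc + eqtime + 4.0 * longitude) % 1440.0
    ha = tst / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0
    ha_rad = math.radians(ha)

    lat_rad = math.radians(latitude)
    cos_zen = math.sin(lat_rad) * math.sin(decl) + math.cos(lat_rad) * math.cos(decl) * math.cos(ha_rad)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))

    sin_zen = math.sin(math.radians(zenith))
    if sin_zen < 1e-9:
        azimuth = 180.0  # sun at zenith: azimuth degenerate
    else:
        cos_az = (math.sin(lat_rad) * cos_zen - math.sin(decl)) / (math.cos(lat_rad) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.degrees(math.acos(cos_az))
        if ha > 0.0:
            azimuth = (az + 180.0) % 360.0
        else:
            azimuth = (540.0 - az) % 360.0

    return SolarGeometry(
        local_datetime=when,
        latitude=latitude,
        longitude=longitude,
        zenith=zenith,
        azimuth=azimuth,
    )
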