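"""Clear-sky solar geometry for the synthetic forcing generator.

Deliberately simple: spherical geometry plus a broadband beam
transmittance raised to the relative air mass.  The point is not
radiative-transfer accuracy but a latitude-controlled, right-skewed
annual distribution of incoming shortwave radiation — the feature that
drives the gap-filling sampling bias at northern sites.
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 1361.0  # W m⁻²
DEFAULT_TRANSMITTANCE = 0.75


def solar_declination(day_of_year):
    """Solar declination in degrees (cosine approximation, ±23.44° extremes)."""
    doy = np.asarray(day_of_year, dtype=float)
    return -23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25)


def cos_zenith(latitude: float, declination, hour_angle):
    """Cosine of the solar zenith angle.

    ``declination`` and ``hour_angle`` in degrees; hour angle 0 at solar
    noon, 15° per hour.
    """
    if np.abs(latitude) > 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    phi = np.deg2rad(latitude)
    delta = np.deg2rad(np.asarray(declination, dtype=float))
    h = np.deg2rad(np.asarray(hour_angle, dtype=float))
    return np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)


def potential_swr(
    latitude: float,
    day_of_year,
    half_hour_of_day,
    solar_constant: float = SOLAR_CONSTANT,
    transmittance: float = DEFAULT_TRANSMITTANCE,
):
    """Clear-sky incoming shortwave radiation, W m⁻².

    Computed as ``S0 * τ**(1/cosZ) * cosZ`` at the mid-point of the half
    hour, clipped to 0 when the sun is below the horizon.  Deterministic.

    Parameters
    ----------
    half_hour_of_day
        Half-hour-of-day slot, 0..47; the sun position is evaluated at the
        slot mid-point (slot 24 → 12:15 local solar time).
    """
    slot = np.asarray(half_hour_of_day, dtype=float)
    if np.any(slot < 0) or np.any(slot > 47):
        raise ValueError("half_hour_of_day must be in 0..47")
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year must be in 1..366")
    hours = slot / 2.0 + 0.25
    hour_angle = (hours - 12.0) * 15.0
    mu = cos_zenith(latitude, solar_declination(doy), hour_angle)
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    up = mu > 0.0
    out[up] = solar_constant * transmittance ** (1.0 / mu[up]) * mu[up]
    if out.ndim == 0:
        return float(out)
    return out
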