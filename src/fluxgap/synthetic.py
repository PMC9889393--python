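"""Synthetic gap-free flux years.

This module builds full half-hourly years of NEE with the statistical
structure that matters for evaluating gap-filling methods at northern
latitudes:

* incoming shortwave radiation whose annual distribution grows more
  right-skewed with latitude (clear-sky geometry × an autocorrelated
  stochastic cloud process),
* NEE as a smooth, concave function of radiation (rectangular-hyperbola
  light response) with Q10 respiration and a VPD limitation,
* heteroscedastic noise resampled from pools binned by season ×
  time-of-day × air-temperature quintile.

Because the truth is known exactly, any discrepancy between a gap-filled
series and the complete series is attributable to the filler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .series import FluxSeries, RECORDS_PER_DAY, year_index
from .solar import DEFAULT_TRANSMITTANCE, SOLAR_CONSTANT, potential_swr

#: Radiation threshold (W m⁻²) separating night from day when binning
#: noise residuals: night is swr <= NIGHT_SWR_MAX.
NIGHT_SWR_MAX = 20.0
#: Months counted as winter for the noise-residual season split.
WINTER_MONTHS = frozenset({1, 2, 3, 4, 11, 12})


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ForcingConfig:
    """Parameters of the stochastic meteorological driver generator."""

    latitude: float = 62.0
    year: int = 2015
    solar_constant: float = SOLAR_CONSTANT
    clear_sky_transmittance: float = DEFAULT_TRANSMITTANCE
    cloud_persistence: float = 0.6  # lag-1 autocorrelation of daily cloudiness
    #: Beta shape pair for the daily cloud fraction; None derives a pair
    #: whose mean rises with |latitude| (boreal climates are cloudier).
    cloud_beta_params: tuple[float, float] | None = None
    cloud_attenuation: float = 0.9  # SWR reduction at full overcast
    tair_annual_mean: float = 4.0  # °C
    tair_annual_amplitude: float = 13.0  # °C, half peak-to-trough
    tair_diurnal_amplitude: float = 6.0  # °C, peak-to-trough
    seed: int = 0

    def validate(self) -> None:
        if np.abs(self.latitude) > 90:
            raise ValueError("latitude outside [-90, 90]")
        if not 0.0 < self.clear_sky_transmittance <= 1.0:
            raise ValueError("clear_sky_transmittance must be in (0, 1]")
        if not 0.0 <= self.cloud_persistence < 1.0:
            raise ValueError("cloud_persistence must be in [0, 1)")
        if not 0.0 <= self.cloud_attenuation <= 1.0:
            raise ValueError("cloud_attenuation must be in [0, 1]")
        if self.cloud_beta_params is not None and min(self.cloud_beta_params) <= 0:
            raise ValueError("cloud_beta_params must be positive")
        if self.tair_annual_amplitude < 0 or self.tair_diurnal_amplitude < 0:
            raise ValueError("temperature amplitudes must be >= 0")


@dataclass
class TruthModel:
    """Parametric generating model for noise-free NEE.

    NEE = R − GPP with Q10 respiration R = r10·q10^((T−10)/10) and a
    saturating light response GPP = season(doy)·pmax·SWR/(k_half+SWR)·
    exp(−vpd_sensitivity·VPD).  Concavity of GPP in SWR is the property
    the sampling-bias mechanism depends on.
    """

    pmax: float = 18.0  # µmol m⁻² s⁻¹, GPP asymptote
    k_half: float = 170.0  # W m⁻², half-saturation radiation
    r10: float = 2.2  # µmol m⁻² s⁻¹, respiration at 10 °C
    q10: float = 2.1
    vpd_sensitivity: float = 0.015  # hPa⁻¹
    season_start: float = 115.0  # day of year, spring onset midpoint
    season_end: float = 280.0  # day of year, autumn decline midpoint
    season_ramp: float = 14.0  # days, logistic steepness

    def validate(self) -> None:
        if self.pmax < 0 or self.r10 < 0 or self.vpd_sensitivity < 0:
            raise ValueError("pmax, r10 and vpd_sensitivity must be >= 0")
        if self.k_half <= 0:
            raise ValueError("k_half must be > 0")
        if self.q10 <= 1:
            raise ValueError("q10 must be > 1")

    def season(self, day_of_year):
        """Growing-season modulation of pmax, smooth in (0, 1)."""
        doy = np.asarray(day_of_year, dtype=float)
        up = 1.0 / (1.0 + np.exp(-(doy - self.season_start) / self.season_ramp))
        down = 1.0 / (1.0 + np.exp((doy - self.season_end) / self.season_ramp))
        return up * down


def truth_nee(model: TruthModel, swr, tair, vpd, day_of_year):
    """Noise-free NEE (µmol m⁻² s⁻¹) from the parametric truth model."""
    model.validate()
    swr = np.asarray(swr, dtype=float)
    if np.any(swr < 0):
        raise ValueError("swr must be non-negative")
    tair = np.asarray(tair, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    resp = model.r10 * model.q10 ** ((tair - 10.0) / 10.0)
    light = swr / (model.k_half + swr)
    vpd_term = np.exp(-model.vpd_sensitivity * np.maximum(vpd, 0.0))
    gpp = model.season(day_of_year) * model.pmax * light * vpd_term
    out = resp - gpp
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# meteorological forcing
# ---------------------------------------------------------------------------


def _daily_cloud_fraction(n_days: int, config: ForcingConfig, rng) -> np.ndarray:
    """AR(1) Gaussian copula mapped to a Beta marginal, one value per day."""
    rho = config.cloud_persistence
    z = np.empty(n_days)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n_days)
    for d in range(1, n_days):
        z[d] = rho * z[d - 1] + np.sqrt(1.0 - rho**2) * eps[d]
    u = sps.norm.cdf(z)
    if config.cloud_beta_params is None:
        # cloudier mean at higher latitude, fixed concentration
        mean = np.clip(0.42 + 0.0045 * abs(config.latitude), 0.0, 0.85)
        conc = 1.5
        a, b = mean * conc, (1.0 - mean) * conc
    else:
        a, b = config.cloud_beta_params
    return sps.beta.ppf(u, a, b)


def _saturation_vp(tair_c: np.ndarray) -> np.ndarray:
    """Magnus saturation vapour pressure over water, hPa."""
    return 6.112 * np.exp(17.62 * tair_c / (243.12 + tair_c))


def generate_forcing(config: ForcingConfig, seed: int | None = None) -> FluxSeries:
    """One full year of half-hourly drivers; NEE is all-NaN.

    SWR is clear-sky potential radiation attenuated by a persistent daily
    cloud process plus mild within-day variability; air temperature is an
    annual + diurnal sinusoid with autocorrelated noise and a cloudiness
    coupling; VPD follows from temperature and cloudiness through a Magnus
    saturation curve; soil temperature is a damped, lagged filter of air
    temperature.  Fully reproducible for a fixed seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    time = year_index(config.year)
    n = len(time)
    n_days = n // RECORDS_PER_DAY
    doy = time.dayofyear.to_numpy()
    slot = (time.hour * 2 + time.minute // 30).to_numpy()

    pot = potential_swr(
        config.latitude,
        doy,
        slot,
        solar_constant=config.solar_constant,
        transmittance=config.clear_sky_transmittance,
    )
    cloud_daily = _daily_cloud_fraction(n_days, config, rng)
    cloud = np.repeat(cloud_daily, RECORDS_PER_DAY)[:n]
    # within-day multiplicative flicker around the daily cloud factor
    flicker = np.clip(1.0 + 0.12 * rng.standard_normal(n), 0.0, None)
    swr = pot * (1.0 - config.cloud_attenuation * cloud) * flicker
    swr = np.clip(swr, 0.0, None)

    # air temperature: annual cycle (min mid-Jan), diurnal cycle (max 14:00),
    # cloudy days damped toward the mean, plus AR(1) weather noise
    annual = -np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
    hours = slot / 2.0 + 0.25
    diurnal = -np.cos(2.0 * np.pi * (hours - 2.0) / 24.0)
    ar = np.empty(n)
    ar[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for i in range(1, n):
        ar[i] = 0.97 * ar[i - 1] + np.sqrt(1 - 0.97**2) * eps[i]
    tair = (
        config.tair_annual_mean
        + config.tair_annual_amplitude * annual
        + 0.5 * config.tair_diurnal_amplitude * diurnal * (1.0 - 0.6 * cloud)
        + 2.0 * ar
    )

    # relative humidity rises with cloudiness; VPD = (1 - RH) * es(T)
    rh = np.clip(0.55 + 0.35 * cloud + 0.08 * rng.standard_normal(n), 0.25, 1.0)
    vpd = np.clip((1.0 - rh) * _saturation_vp(tair), 0.0, None)

    # damped, lagged soil temperature: exponential moving average over ~10 d
    alpha = 1.0 / (10.0 * RECORDS_PER_DAY)
    tsoil = np.empty(n)
    tsoil[0] = config.tair_annual_mean
    for i in range(1, n):
        tsoil[i] = tsoil[i - 1] + alpha * (tair[i] - tsoil[i - 1])

    return FluxSeries(
        time=time,
        nee=np.full(n, np.nan),
        qc=np.full(n, 1, dtype=np.int64),
        swr=swr,
        tair=tair,
        vpd=vpd,
        tsoil=tsoil,
        latitude=config.latitude,
    )


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Residual pools binned by season × time-of-day × tair quintile.

    Twenty bins: {winter, summer} × {night, day} × five equal-count air
    temperature bins (edges from the series the model was fitted on).
    """

    tair_edges: np.ndarray  # 4 interior quintile edges
    pools: list = field(default_factory=list)  # 20 arrays of residuals
    night_swr_max: float = NIGHT_SWR_MAX

    N_BINS = 20

    def bin_index(self, month, swr, tair) -> np.ndarray:
        """Map records to bins 0..19; every record maps to exactly one."""
        month = np.asarray(month)
        swr = np.asarray(swr, dtype=float)
        tair = np.asarray(tair, dtype=float)
        winter = np.isin(month, list(WINTER_MONTHS))
        night = swr <= self.night_swr_max
        quintile = np.searchsorted(self.tair_edges, tair, side="right")
        return (
            np.where(winter, 0, 1) * 10 + np.where(night, 0, 1) * 5 + quintile
        )

    @staticmethod
    def bin_label(index: int) -> str:
        season = "winter" if index < 10 else "summer"
        diel = "night" if (index % 10) < 5 else "day"
        return f"{season}/{diel}/tair-q{index % 5 + 1}"


def fit_noise_model(
    clean: FluxSeries,
    noisy_or_residuals,
    night_swr_max: float = NIGHT_SWR_MAX,
    require_all_bins: bool = False,
) -> NoiseModel:
    """Partition residuals into the 20 season × diel × tair-quintile bins.

    ``noisy_or_residuals`` is either an array of residuals aligned with
    ``clean`` or a noisy :class:`FluxSeries` on the same timestamps (the
    residual is then ``noisy.nee − clean.nee``).

    Season and temperature are strongly correlated, so some bins (e.g.
    winter nights in the warmest temperature quintile) receive no records
    at boreal sites; by default those pools are simply left empty, and
    :func:`inject_noise` raises if a record ever maps to an empty pool.
    ``require_all_bins=True`` demands every bin be populated and raises a
    configuration error naming the first empty one.
    """
    if isinstance(noisy_or_residuals, FluxSeries):
        if not clean.time.equals(noisy_or_residuals.time):
            raise ValueError("clean and noisy series must share timestamps")
        residuals = noisy_or_residuals.nee - clean.nee
    else:
        residuals = np.asarray(noisy_or_residuals, dtype=float)
        if residuals.shape != clean.nee.shape:
            raise ValueError("residuals must align with the clean series")
    edges = np.quantile(clean.tair, [0.2, 0.4, 0.6, 0.8])
    model = NoiseModel(tair_edges=edges, night_swr_max=night_swr_max)
    idx = model.bin_index(clean.month, clean.swr, clean.tair)
    finite = np.isfinite(residuals)
    model.pools = [residuals[finite & (idx == b)] for b in range(NoiseModel.N_BINS)]
    if require_all_bins:
        for b, pool in enumerate(model.pools):
            if pool.size == 0:
                raise ValueError(f"empty residual bin: {NoiseModel.bin_label(b)}")
    return model


def default_noise_model(
    clean: FluxSeries,
    seed: int,
    base_sd: float = 0.6,
    relative_sd: float = 0.25,
) -> NoiseModel:
    """Heteroscedastic parametric residual pools for pure-synthetic use.

    Per-record residuals are Laplace-distributed (heavy-tailed, as flux
    random error is observed to be) with standard deviation
    ``base_sd + relative_sd·|NEE|`` — the magnitude-proportional scaling
    reported for eddy-covariance random error, at the middle of the
    published forest-site range — then pooled by bin exactly as fitted
    residuals would be, so large-flux bins carry wider pools.
    """
    rng = np.random.default_rng(seed)
    sd = base_sd + relative_sd * np.abs(clean.nee)
    residuals = rng.laplace(0.0, sd / np.sqrt(2.0))
    return fit_noise_model(clean, residuals)


def inject_noise(clean: FluxSeries, noise: NoiseModel, seed: int) -> FluxSeries:
    """Add a residual drawn with replacement from each record's bin pool."""
    rng = np.random.default_rng(seed)
    idx = noise.bin_index(clean.month, clean.swr, clean.tair)
    draws = np.empty(len(clean))
    for b in range(NoiseModel.N_BINS):
        sel = idx == b
        k = int(sel.sum())
        if k == 0:
            continue
        pool = noise.pools[b]
        if pool.size == 0:
            raise ValueError(f"empty residual bin: {NoiseModel.bin_label(b)}")
        draws[sel] = pool[rng.integers(0, pool.size, size=k)]
    out = clean.copy()
    out.nee = clean.nee + draws
    return out


# ---------------------------------------------------------------------------
# one-call synthetic year
# ---------------------------------------------------------------------------


def make_synthetic_year(
    forcing: ForcingConfig | None = None,
    truth: TruthModel | None = None,
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> tuple[FluxSeries, FluxSeries]:
    """Generate a gap-free (clean, noisy) pair of synthetic flux years.

    The clean series carries noise-free truth NEE; the noisy series adds
    bin-resampled heteroscedastic residuals and is the stand-in for
    "measured" data (qc = 0 everywhere).  Sub-seeds for forcing, the
    default noise model and the injection are spawned from ``seed``.
    """
    forcing = forcing if forcing is not None else ForcingConfig()
    truth = truth if truth is not None else TruthModel()
    ss = np.random.SeedSequence(seed)
    s_forcing, s_noise_fit, s_noise_draw = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    drivers = generate_forcing(forcing, seed=s_forcing)
    nee = truth_nee(truth, drivers.swr, drivers.tair, drivers.vpd, drivers.day_of_year)
    clean = replace(
        drivers, nee=np.asarray(nee), qc=np.zeros(len(drivers), dtype=np.int64)
    )
    if noise is None:
        noise = default_noise_model(clean, seed=s_noise_fit)
    noisy = inject_noise(clean, noise, seed=s_noise_draw)
    return clean, noisy
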