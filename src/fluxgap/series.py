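"""Half-hourly flux time-series container.

A :class:`FluxSeries` holds one (or part of one) year of half-hourly net
ecosystem exchange (NEE) together with the meteorological drivers used for
gap-filling: incoming shortwave radiation (SWR), air temperature, vapour
pressure deficit (VPD) and, optionally, soil temperature.  It is the common
currency passed between the generator, the gap engine, the fillers and the
evaluation code.

Sign convention is micrometeorological: positive NEE is a flux from the
ecosystem to the atmosphere (emission), negative is uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HALF_HOUR_SECONDS = 1800
RECORDS_PER_DAY = 48


class FluxSeriesError(ValueError):
    """Structural problem with a half-hourly flux series."""


@dataclass
class FluxSeries:
    """One stretch of half-hourly flux records.

    Parameters
    ----------
    time
        Timestamps of interval starts, local standard time (no DST),
        strictly increasing with a constant 30-minute step.
    nee
        Net ecosystem exchange, µmol CO2 m⁻² s⁻¹; NaN marks missing.
    qc
        Integer quality flag per record; 0 means a direct measurement.
        A record is "measured" iff ``qc == 0`` and ``nee`` is finite.
    swr
        Incoming shortwave radiation, W m⁻², non-negative.
    tair
        Air temperature, °C.
    vpd
        Vapour pressure deficit, hPa, non-negative where finite.
    tsoil
        Soil temperature, °C (optional driver).
    latitude
        Site latitude in decimal degrees; carried out-of-band because
        FLUXNET-archive files do not store it.
    """

    time: pd.DatetimeIndex
    nee: np.ndarray
    qc: np.ndarray
    swr: np.ndarray
    tair: np.ndarray
    vpd: np.ndarray
    tsoil: np.ndarray | None = None
    latitude: float = float("nan")
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        n = len(self.time)
        self.nee = np.asarray(self.nee, dtype=float)
        self.qc = np.asarray(self.qc, dtype=np.int64)
        self.swr = np.asarray(self.swr, dtype=float)
        self.tair = np.asarray(self.tair, dtype=float)
        self.vpd = np.asarray(self.vpd, dtype=float)
        if self.tsoil is not None:
            self.tsoil = np.asarray(self.tsoil, dtype=float)
        for name in ("nee", "qc", "swr", "tair", "vpd"):
            if len(getattr(self, name)) != n:
                raise FluxSeriesError(
                    f"column '{name}' has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if self.tsoil is not None and len(self.tsoil) != n:
            raise FluxSeriesError("column 'tsoil' length mismatch")
        if n == 0:
            raise FluxSeriesError("empty series")
        steps = np.diff(self.time.asi8)
        if n > 1 and not np.all(steps == HALF_HOUR_SECONDS * 10**9):
            raise FluxSeriesError(
                "timestamps must be strictly increasing with a constant "
                "30-minute step"
            )
        finite_swr = self.swr[np.isfinite(self.swr)]
        if finite_swr.size and finite_swr.min() < 0:
            raise FluxSeriesError("swr must be non-negative")
        self._validated = True

    # -- derived views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.time)

    @property
    def measured(self) -> np.ndarray:
        """Boolean mask of directly measured records (qc==0 and finite NEE)."""
        return (self.qc == 0) & np.isfinite(self.nee)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of records whose NEE is not usable."""
        return ~self.measured

    @property
    def slot(self) -> np.ndarray:
        """Half-hour-of-day index, 0..47."""
        return (self.time.hour * 2 + self.time.minute // 30).to_numpy()

    @property
    def day_of_year(self) -> np.ndarray:
        return self.time.dayofyear.to_numpy()

    @property
    def month(self) -> np.ndarray:
        return self.time.month.to_numpy()

    def copy(self) -> "FluxSeries":
        return replace(
            self,
            nee=self.nee.copy(),
            qc=self.qc.copy(),
            swr=self.swr.copy(),
            tair=self.tair.copy(),
            vpd=self.vpd.copy(),
            tsoil=None if self.tsoil is None else self.tsoil.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (one row per half hour)."""
        data = {
            "nee": self.nee,
            "qc": self.qc,
            "swr": self.swr,
            "tair": self.tair,
            "vpd": self.vpd,
        }
        if self.tsoil is not None:
            data["tsoil"] = self.tsoil
        return pd.DataFrame(data, index=self.time)

    def equals(self, other: "FluxSeries") -> bool:
        """Bit-level equality of timestamps and all stored columns."""
        same = (
            self.time.equals(other.time)
            and np.array_equal(self.nee, other.nee, equal_nan=True)
            and np.array_equal(self.qc, other.qc)
            and np.array_equal(self.swr, other.swr, equal_nan=True)
            and np.array_equal(self.tair, other.tair, equal_nan=True)
            and np.array_equal(self.vpd, other.vpd, equal_nan=True)
        )
        if not same:
            return False
        if (self.tsoil is None) != (other.tsoil is None):
            return False
        if self.tsoil is not None:
            return np.array_equal(self.tsoil, other.tsoil, equal_nan=True)
        return True


def year_index(year: int) -> pd.DatetimeIndex:
    """Half-hourly interval-start timestamps covering one calendar year."""
    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=1)
    return pd.date_range(start, end, freq="30min", inclusive="left")
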