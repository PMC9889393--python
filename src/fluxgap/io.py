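"""Reading and writing FLUXNET-archive-dialect half-hourly CSV files.

The dialect is the one used by the FLUXNET2015 and ICOS Warm Winter 2020
releases: a flat CSV with ``TIMESTAMP_START``/``TIMESTAMP_END`` columns in
``YYYYMMDDHHMM`` local standard time and ``-9999`` as the missing-value
sentinel.  Only the variables needed for NEE gap-filling are handled:
``NEE_VUT_REF`` with its quality flag ``NEE_VUT_REF_QC``, ``SW_IN_F``,
``TA_F_MDS``, ``VPD_F_MDS`` and (optionally) ``TS_F_MDS_1``.

On reading, NEE is masked to NaN wherever the quality flag is non-zero or
the value is the sentinel; driver columns are kept even where NEE is
missing, because FLUXNET drivers are gap-filled upstream.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .series import FluxSeries, FluxSeriesError

MISSING = -9999.0

REQUIRED_COLUMNS = (
    "TIMESTAMP_START",
    "NEE_VUT_REF",
    "NEE_VUT_REF_QC",
    "SW_IN_F",
    "TA_F_MDS",
    "VPD_F_MDS",
)
TSOIL_COLUMN = "TS_F_MDS_1"


class FluxFileFormatError(FluxSeriesError):
    """The file does not follow the FLUXNET-archive dialect."""


def _decode(values: pd.Series) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    arr = arr.copy()
    arr[arr == MISSING] = np.nan
    return arr


def read_fluxnet_csv(path, latitude: float = float("nan")) -> FluxSeries:
    """Read a FLUXNET-archive CSV into a :class:`FluxSeries`.

    NEE is retained only where ``NEE_VUT_REF_QC == 0`` and the value is not
    the ``-9999`` sentinel; everything else becomes NaN.  ``latitude`` is
    supplied out-of-band (FLUXNET files do not carry it).
    """
    df = pd.read_csv(
        path, dtype={"TIMESTAMP_START": str}, float_precision="round_trip"
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FluxFileFormatError(f"missing required column '{col}'")
    try:
        time = pd.to_datetime(df["TIMESTAMP_START"], format="%Y%m%d%H%M")
    except (ValueError, TypeError) as exc:
        raise FluxFileFormatError(f"bad TIMESTAMP_START values: {exc}") from exc
    qc = df["NEE_VUT_REF_QC"].to_numpy(dtype=np.int64)
    nee = _decode(df["NEE_VUT_REF"])
    nee[qc != 0] = np.nan
    tsoil = _decode(df[TSOIL_COLUMN]) if TSOIL_COLUMN in df.columns else None
    return FluxSeries(
        time=pd.DatetimeIndex(time),
        nee=nee,
        qc=qc,
        swr=_decode(df["SW_IN_F"]),
        tair=_decode(df["TA_F_MDS"]),
        vpd=_decode(df["VPD_F_MDS"]),
        tsoil=tsoil,
        latitude=latitude,
    )


def _encode(arr: np.ndarray) -> list:
    # shortest-round-trip repr keeps float64 values bit-exact through the file
    return ["-9999" if not np.isfinite(v) else repr(float(v)) for v in arr]


def write_fluxnet_csv(series: FluxSeries, path) -> None:
    """Write a :class:`FluxSeries` as FLUXNET-archive CSV.

    NaN is written as ``-9999``; finite values are written with full
    precision so that ``read(write(s))`` reproduces ``s`` bit-identically.
    """
    if len(series) == 0:  # pragma: no cover - constructor forbids it
        raise FluxSeriesError("refusing to write an empty series")
    end = series.time + pd.Timedelta(minutes=30)
    df = pd.DataFrame(
        {
            "TIMESTAMP_START": series.time.strftime("%Y%m%d%H%M"),
            "TIMESTAMP_END": end.strftime("%Y%m%d%H%M"),
            "NEE_VUT_REF": _encode(series.nee),
            "NEE_VUT_REF_QC": series.qc,
            "SW_IN_F": _encode(series.swr),
            "TA_F_MDS": _encode(series.tair),
            "VPD_F_MDS": _encode(series.vpd),
        }
    )
    if series.tsoil is not None:
        df[TSOIL_COLUMN] = _encode(series.tsoil)
    df.to_csv(path, index=False)


def load_northern_sites() -> pd.DataFrame:
    """Bundled table of the ten northern (60–68°N) reference sites.

    Columns: site id, year, name, country, latitude, longitude, site type
    and annual measured-data coverage.  Used as a source of realistic
    latitudes/years for the synthetic generator.
    """
    ref = importlib.resources.files("fluxgap.data") / "northern_sites.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
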