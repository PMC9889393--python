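import numpy as np
import pandas as pd
import pytest

from fluxgap import FluxSeries, MDSConfig, default_catalogue, make_synthetic_year


def make_series(
    n,
    nee=None,
    qc=None,
    swr=None,
    tair=None,
    vpd=None,
    tsoil=None,
    start="2015-01-01",
    latitude=62.0,
):
    """Small hand-built FluxSeries with sensible defaults."""
    time = pd.date_range(start, periods=n, freq="30min")
    return FluxSeries(
        time=time,
        nee=np.zeros(n) if nee is None else np.asarray(nee, dtype=float),
        qc=np.zeros(n, dtype=int) if qc is None else np.asarray(qc),
        swr=np.zeros(n) if swr is None else np.asarray(swr, dtype=float),
        tair=np.full(n, 10.0) if tair is None else np.asarray(tair, dtype=float),
        vpd=np.full(n, 3.0) if vpd is None else np.asarray(vpd, dtype=float),
        tsoil=tsoil,
        latitude=latitude,
    )


@pytest.fixture(scope="session")
def year_pair():
    """One default synthetic (clean, noisy) year at 62°N, seed 1."""
    return make_synthetic_year(seed=1)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue(seed=0)


@pytest.fixture()
def standard_config():
    return MDSConfig.preset("standard")
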