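"""Marginal distribution sampling (MDS) gap-filling, from scratch.

MDS fills a missing half-hourly NEE value with the average of fluxes
measured under similar meteorological conditions inside a moving time
window.  "Similar" means within fixed tolerances of the conditions at the
gap: shortwave radiation within 20 W m⁻² when the gap's SWR is ≤ 50 W m⁻²
and within 50 W m⁻² above that, air temperature within 2.5 K and vapour
pressure deficit within 5 hPa.  If air temperature or VPD is missing at
the gap only SWR is used; if no driver is available the mean diurnal
course (MDC — same time of day ± 1 h on neighbouring days) is used.

The window cascade widens until a sufficiently large sample is found.
The exact schedule is configurable (``MDSConfig.window_schedule``); the
default is the conventional lookup-table cascade:

1. all drivers, ± 7 then ± 14 days;
2. SWR only, ± 7 days;
3. MDC at ± 0, ± 1, ± 2 days;
4. all drivers widening by 7 days up to ± 70;
5. SWR only widening up to ± 70;
6. MDC widening up to ± 210 days.

Besides the standard tolerances three modified variants are provided:
``narrowed`` ([10, 25] W m⁻² SWR tolerances), ``single_tol`` (one 25 W m⁻²
tolerance at all radiation levels) and ``subsample_mean`` (for daytime
gaps, average the mean NEE of the below-target-SWR and above-target-SWR
subsamples instead of the pooled mean — a direct correction for the
sampling bias caused by skewed radiation distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .gaps import GapPlan
from .series import FluxSeries

KIND_ALL, KIND_SWR, KIND_MDC = 0, 1, 2
_KIND_NAMES = {KIND_ALL: "all", KIND_SWR: "swr", KIND_MDC: "mdc"}

#: Daytime threshold used by the subsample variant, W m⁻².
DAY_SWR_MIN = 20.0

UNFILLED = -2
MEASURED = -1


def default_window_schedule() -> list[tuple[int, int]]:
    """The conventional cascade as (kind, halfwidth-in-days) steps."""
    schedule = [
        (KIND_ALL, 7),
        (KIND_ALL, 14),
        (KIND_SWR, 7),
        (KIND_MDC, 0),
        (KIND_MDC, 1),
        (KIND_MDC, 2),
    ]
    schedule += [(KIND_ALL, hw) for hw in range(21, 71, 7)]
    schedule += [(KIND_SWR, hw) for hw in range(14, 71, 7)]
    schedule += [(KIND_MDC, hw) for hw in range(7, 211, 7)]
    return schedule


@dataclass
class MDSConfig:
    """Tolerances, variant and window schedule of one MDS flavour."""

    swr_tol_low: float = 20.0  # W m⁻², applies when gap SWR <= breakpoint
    swr_tol_high: float = 50.0  # W m⁻²
    swr_breakpoint: float = 50.0  # W m⁻²; ties take the low tolerance
    tair_tol: float = 2.5  # K
    vpd_tol: float = 5.0  # hPa
    variant: str = "standard"
    min_sample: int = 2
    day_swr_min: float = DAY_SWR_MIN
    window_schedule: list = field(default_factory=default_window_schedule)

    def __post_init__(self) -> None:
        if min(self.swr_tol_low, self.swr_tol_high, self.tair_tol, self.vpd_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_sample < 1:
            raise ValueError("min_sample must be >= 1")
        if self.variant not in (
            "standard",
            "narrowed",
            "single_tol",
            "subsample_mean",
        ):
            raise ValueError(f"unknown variant '{self.variant}'")

    @classmethod
    def preset(cls, variant: str) -> "MDSConfig":
        """Named presets: SWR tolerances [20, 50], [10, 25], [25, 25] and
        the subsample-averaging correction (with standard tolerances)."""
        if variant == "standard":
            return cls(variant="standard")
        if variant == "narrowed":
            return cls(swr_tol_low=10.0, swr_tol_high=25.0, variant="narrowed")
        if variant == "single_tol":
            return cls(swr_tol_low=25.0, swr_tol_high=25.0, variant="single_tol")
        if variant == "subsample_mean":
            return cls(variant="subsample_mean")
        raise ValueError(f"unknown variant '{variant}'")

    def step_label(self, step: int) -> str:
        kind, hw = self.window_schedule[step]
        return f"{_KIND_NAMES[kind]}±{hw}d"


@dataclass
class FillResult:
    """A filled series with per-record provenance.

    ``fill_step`` holds the index of the cascade step that produced each
    fill (−1 for untouched records, −2 for unfillable gaps) and
    ``sample_size`` the number of candidates averaged.
    """

    nee_filled: np.ndarray
    fill_step: np.ndarray
    sample_size: np.ndarray
    mask: np.ndarray
    config: object = None

    @property
    def n_unfilled(self) -> int:
        return int((self.fill_step == UNFILLED).sum())

    @property
    def filled(self) -> np.ndarray:
        return self.fill_step >= 0

    def quality(self) -> np.ndarray:
        """QC-like tier per record: 0 measured/untouched, 1 best fills
        (full-similarity ≤ ±14 d or near MDC), 2 widened lookups, 3 far
        MDC, −1 unfilled."""
        q = np.zeros(self.nee_filled.size, dtype=np.int64)
        if isinstance(self.config, MDSConfig):
            sched = self.config.window_schedule
        else:
            sched = None
        for i in np.flatnonzero(self.fill_step != MEASURED):
            s = self.fill_step[i]
            if s == UNFILLED:
                q[i] = -1
            elif sched is None:
                q[i] = 1
            else:
                kind, hw = sched[s]
                if (kind == KIND_ALL and hw <= 14) or (kind == KIND_MDC and hw <= 2):
                    q[i] = 1
                elif kind == KIND_MDC:
                    q[i] = 3
                else:
                    q[i] = 2
        return q


# ---------------------------------------------------------------------------
# elementary pieces (also used by diagnostics and tests)
# ---------------------------------------------------------------------------


def swr_tolerance(config: MDSConfig, target_swr: float) -> float:
    """Radiation tolerance at a gap: low band at/below the breakpoint."""
    if target_swr < 0:
        raise ValueError("target_swr must be >= 0")
    return config.swr_tol_low if target_swr <= config.swr_breakpoint else config.swr_tol_high


def sample_candidates(
    series: FluxSeries,
    gap_index: int,
    window_halfwidth: int,
    config: MDSConfig,
    use_all_drivers: bool = True,
    exclude: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Measured (nee, swr) pairs similar to the gap within ± halfwidth days.

    ``exclude`` optionally hides records (e.g. other artificial gaps) from
    the candidate pool; the gap record itself is always excluded.
    """
    n = len(series)
    tswr = series.swr[gap_index]
    tol = swr_tolerance(config, tswr)
    lo = max(0, gap_index - window_halfwidth * 48)
    hi = min(n, gap_index + window_halfwidth * 48 + 1)
    sel = series.measured[lo:hi].copy()
    if exclude is not None:
        sel &= ~exclude[lo:hi]
    sel[gap_index - lo] = False
    with np.errstate(invalid="ignore"):
        sel &= np.abs(series.swr[lo:hi] - tswr) <= tol
        if use_all_drivers:
            sel &= np.abs(series.tair[lo:hi] - series.tair[gap_index]) <= config.tair_tol
            sel &= np.abs(series.vpd[lo:hi] - series.vpd[gap_index]) <= config.vpd_tol
    idx = np.flatnonzero(sel) + lo
    return [(float(series.nee[j]), float(series.swr[j])) for j in idx]


def fill_gap_subsample_variant(
    candidates: list[tuple[float, float]],
    target_swr: float,
    daytime: bool,
) -> float:
    """The subsample-averaging fill rule on an explicit candidate list.

    Daytime: average the mean NEE of the below-target and above-target SWR
    subsamples; candidates at exactly the target SWR belong to neither.
    Single-sided or nighttime cases fall back to the plain mean.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    nee = np.array([c[0] for c in candidates])
    swr = np.array([c[1] for c in candidates])
    if daytime:
        lo = nee[swr < target_swr]
        hi = nee[swr > target_swr]
        if lo.size and hi.size:
            return 0.5 * (lo.mean() + hi.mean())
    return float(nee.mean())


# ---------------------------------------------------------------------------
# the cascade kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_kernel(
    nee,
    swr,
    tair,
    vpd,
    slot,
    cand,
    targets,
    tol_low,
    tol_high,
    swr_breakpoint,
    tair_tol,
    vpd_tol,
    min_sample,
    subsample,
    day_thresh,
    step_kind,
    step_hw,
):  # pragma: no cover - exercised via fill_series (numba-compiled)
    n = nee.shape[0]
    m = targets.shape[0]
    n_steps = step_kind.shape[0]
    values = np.full(m, np.nan)
    steps_out = np.full(m, -2, np.int64)
    sizes = np.zeros(m, np.int64)
    for ti in range(m):
        g = targets[ti]
        tswr = swr[g]
        ttair = tair[g]
        tvpd = vpd[g]
        have_swr = np.isfinite(tswr)
        have_all = have_swr and np.isfinite(ttair) and np.isfinite(tvpd)
        tol = tol_low
        if have_swr and tswr > swr_breakpoint:
            tol = tol_high
        gslot = slot[g]
        for si in range(n_steps):
            kind = step_kind[si]
            hw = step_hw[si]
            if kind == 0 and not have_all:
                continue
            if kind == 1 and not have_swr:
                continue
            if kind == 2:
                w = hw * 48 + 2  # same slot ±1 h within ±hw days
            else:
                w = hw * 48
            lo = g - w
            if lo < 0:
                lo = 0
            hi = g + w + 1
            if hi > n:
                hi = n
            s_all = 0.0
            c_all = 0
            s_lo = 0.0
            c_lo = 0
            s_hi = 0.0
            c_hi = 0
            for j in range(lo, hi):
                if j == g or not cand[j]:
                    continue
                if kind == 2:
                    d = gslot - slot[j]
                    if d < 0:
                        d = -d
                    if d > 24:
                        d = 48 - d
                    if d > 2:
                        continue
                else:
                    ds = swr[j] - tswr
                    if ds < 0:
                        ds = -ds
                    if not ds <= tol:
                        continue
                    if kind == 0:
                        dt = tair[j] - ttair
                        if dt < 0:
                            dt = -dt
                        if not dt <= tair_tol:
                            continue
                        dv = vpd[j] - tvpd
                        if dv < 0:
                            dv = -dv
                        if not dv <= vpd_tol:
                            continue
                v = nee[j]
                s_all += v
                c_all += 1
                if kind != 2:
                    if swr[j] < tswr:
                        s_lo += v
                        c_lo += 1
                    elif swr[j] > tswr:
                        s_hi += v
                        c_hi += 1
            if c_all >= min_sample:
                if (
                    subsample
                    and kind != 2
                    and have_swr
                    and tswr >= day_thresh
                    and c_lo > 0
                    and c_hi > 0
                ):
                    values[ti] = 0.5 * (s_lo / c_lo + s_hi / c_hi)
                else:
                    values[ti] = s_all / c_all
                steps_out[ti] = si
                sizes[ti] = c_all
                break
    return values, steps_out, sizes


def _run_cascade(series: FluxSeries, targets: np.ndarray, cand: np.ndarray, config: MDSConfig):
    sched = np.array(config.window_schedule, dtype=np.int64)
    return _fill_kernel(
        series.nee,
        series.swr,
        series.tair,
        series.vpd,
        series.slot.astype(np.int64),
        cand,
        targets.astype(np.int64),
        float(config.swr_tol_low),
        float(config.swr_tol_high),
        float(config.swr_breakpoint),
        float(config.tair_tol),
        float(config.vpd_tol),
        int(config.min_sample),
        config.variant == "subsample_mean",
        float(config.day_swr_min),
        sched[:, 0].copy(),
        sched[:, 1].copy(),
    )


# ---------------------------------------------------------------------------
# public fill drivers
# ---------------------------------------------------------------------------


def fill_gap(series: FluxSeries, gap_index: int, config: MDSConfig):
    """Fill a single missing record; returns (value, tier label, sample size).

    The value is NaN (tier ``None``) when even the widest window fails —
    an unfillable gap is flagged, never imputed as zero.
    """
    if series.measured[gap_index]:
        raise ValueError(f"record {gap_index} is measured, not a gap")
    targets = np.array([gap_index], dtype=np.int64)
    values, steps, sizes = _run_cascade(series, targets, series.measured, config)
    if steps[0] == UNFILLED:
        return float("nan"), None, 0
    return float(values[0]), config.step_label(int(steps[0])), int(sizes[0])


def fill_series(series: FluxSeries, plan: GapPlan, config: MDSConfig) -> FillResult:
    """Fill every record masked by ``plan``; masked records are hidden
    from the candidate pool (artificial-gap evaluation mode).

    Records that are missing in the series but not masked by the plan are
    left untouched.  Deterministic.
    """
    mask = plan.mask
    if mask.size != len(series):
        raise ValueError("plan mask length does not match series")
    targets = np.flatnonzero(mask)
    cand = series.measured & ~mask
    nee_out = series.nee.copy()
    step_out = np.full(len(series), MEASURED, dtype=np.int64)
    size_out = np.zeros(len(series), dtype=np.int64)
    if targets.size:
        values, steps, sizes = _run_cascade(series, targets, cand, config)
        nee_out[targets] = values
        step_out[targets] = steps
        size_out[targets] = sizes
    return FillResult(
        nee_filled=nee_out,
        fill_step=step_out,
        sample_size=size_out,
        mask=mask.copy(),
        config=config,
    )


def fill_loo(series: FluxSeries, config: MDSConfig) -> FillResult:
    """Leave-one-out evaluation: fill each measured record with itself
    excluded from its own candidate pool, all other measured records
    available.  Equivalent to iterating single-record plans."""
    targets = np.flatnonzero(series.measured)
    values, steps, sizes = _run_cascade(series, targets, series.measured, config)
    nee_out = series.nee.copy()
    step_out = np.full(len(series), MEASURED, dtype=np.int64)
    size_out = np.zeros(len(series), dtype=np.int64)
    nee_out[targets] = values
    step_out[targets] = steps
    size_out[targets] = sizes
    mask = np.zeros(len(series), dtype=bool)
    mask[targets] = True
    return FillResult(
        nee_filled=nee_out,
        fill_step=step_out,
        sample_size=size_out,
        mask=mask,
        config=config,
    )
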