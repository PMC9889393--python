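"""Performance measures for gap-filled flux series.

Mean bias and RMSE are computed over the artificial-gap records only;
the carbon-balance error integrates the filled series over the whole
year and compares it with the true (synthetic) balance, in
g C m⁻² y⁻¹.  Diagnostics for the radiation-sampling mechanism — the
signed candidate-count sample bias and the skewness of the SWR
distribution — live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .gaps import GapPlan
from .mds import FillResult
from .series import FluxSeries, HALF_HOUR_SECONDS

#: Day/night split for evaluation: day is swr >= 20 W m⁻².
DAY_SWR_MIN = 20.0

#: µmol CO2 m⁻² s⁻¹ × one half hour → g C m⁻²: 1800 s × 12.01 µg µmol⁻¹.
GC_PER_UMOL_HALFHOUR = HALF_HOUR_SECONDS * 12.01e-6


class EmptySplitError(ValueError):
    """No gap records fall in the requested day/night split."""


def _split_mask(swr: np.ndarray, split: str) -> np.ndarray:
    if split == "total":
        return np.ones_like(swr, dtype=bool)
    if split == "day":
        return swr >= DAY_SWR_MIN
    if split == "night":
        return swr < DAY_SWR_MIN
    raise ValueError(f"unknown split '{split}'")


def mean_bias(
    filled: FillResult,
    reference: FluxSeries,
    plan: GapPlan | None = None,
    split: str = "total",
) -> float:
    """Mean of (filled − reference) over masked records in the split.

    Positive bias means emission overestimated or uptake underestimated.
    The day/night split uses the radiation at the gap (day: ≥ 20 W m⁻²).
    """
    mask = filled.mask if plan is None else plan.mask
    sel = mask & filled.filled & _split_mask(reference.swr, split)
    if not sel.any():
        raise EmptySplitError(f"no filled gap records in split '{split}'")
    return float(np.mean(filled.nee_filled[sel] - reference.nee[sel]))


def rmse(
    filled: FillResult, reference: FluxSeries, plan: GapPlan | None = None
) -> float:
    """Root-mean-squared error over masked records."""
    mask = filled.mask if plan is None else plan.mask
    sel = mask & filled.filled
    if not sel.any():
        raise EmptySplitError("no filled gap records")
    return float(np.sqrt(np.mean((filled.nee_filled[sel] - reference.nee[sel]) ** 2)))


def balance_error(filled: FillResult, truth: FluxSeries) -> float:
    """Gap-filled minus true annual carbon balance, g C m⁻² y⁻¹.

    Each half-hourly difference converts as µmol m⁻² s⁻¹ × 1800 s ×
    12.01 × 10⁻⁶ g µmol⁻¹.  Records outside gaps are identical in both
    series, so this equals the sum of per-gap differences.
    """
    if filled.nee_filled.size != len(truth):
        raise ValueError("filled series and truth have different lengths")
    diff = filled.nee_filled - truth.nee
    diff = np.where(np.isfinite(diff), diff, 0.0)  # unfilled gaps contribute 0
    return float(diff.sum() * GC_PER_UMOL_HALFHOUR)


def sample_bias(candidates, target_swr: float) -> int:
    """Signed excess of below-target over above-target SWR candidates.

    Positive values mean the averaging sample is dominated by lower
    radiation levels than the gap's, so the filled NEE is likely to be
    overestimated (photosynthetic uptake underestimated).
    """
    swr = np.array([c[1] for c in candidates], dtype=float)
    return int((swr < target_swr).sum() - (swr > target_swr).sum())


def swr_skewness(series: FluxSeries, subset: str = "all") -> float:
    """Adjusted Fisher–Pearson skewness of the SWR distribution.

    ``subset='daytime'`` restricts to swr ≥ 20 W m⁻².  Constant input has
    undefined skewness and raises.
    """
    swr = series.swr[np.isfinite(series.swr)]
    if subset == "daytime":
        swr = swr[swr >= DAY_SWR_MIN]
    elif subset != "all":
        raise ValueError(f"unknown subset '{subset}'")
    if np.unique(swr).size < 3:
        raise ValueError("skewness undefined for near-constant input")
    return float(sps.skew(swr, bias=False))


@dataclass
class EvalReport:
    """One filled-series evaluation: biases, RMSE, balance error and
    bookkeeping (n_gaps, n_unfilled)."""

    bias_total: float
    bias_day: float
    bias_night: float
    rmse: float
    balance_error: float
    n_gaps: int
    n_unfilled: int = 0
    skewness_swr: float = float("nan")
    p_values: dict = field(default_factory=dict)


def evaluate_fill(
    filled: FillResult,
    reference: FluxSeries,
    truth: FluxSeries | None = None,
) -> EvalReport:
    """Bundle the standard measures for one filled series.

    ``reference`` supplies the hidden values at the artificial gaps (the
    noisy synthetic series in simulation experiments); ``truth`` defaults
    to the reference and is used for the annual balance error.
    """

    def _try(split):
        try:
            return mean_bias(filled, reference, split=split)
        except EmptySplitError:
            return float("nan")

    return EvalReport(
        bias_total=_try("total"),
        bias_day=_try("day"),
        bias_night=_try("night"),
        rmse=rmse(filled, reference),
        balance_error=balance_error(filled, truth if truth is not None else reference),
        n_gaps=int(filled.mask.sum()),
        n_unfilled=filled.n_unfilled,
    )
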