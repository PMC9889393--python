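"""Describing, sampling and inserting missing-data patterns.

Real eddy-covariance records are gappy in a structured way: gaps cluster
at night (low-turbulence filtering) and have a heavy-tailed length
distribution.  This module extracts an empirical catalogue of
(length, start-time-of-day) pairs from a real series, resamples it to
insert realistic non-overlapping artificial gaps into gap-free synthetic
series at a target gap fraction, and produces the two exhaustive
evaluation labellings (leave-one-out and 1 %-fold).

``gap_fraction`` means the fraction of records masked (0.7 = 70 % of the
year turned into artificial gaps), matching how the gap classes are
labelled on result axes; it is not the remaining data coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .series import FluxSeries, RECORDS_PER_DAY

#: Longest gap handled, in half hours (3 days).
MAX_GAP_LEN = 3 * RECORDS_PER_DAY


class GapPlacementError(RuntimeError):
    """Target gap fraction could not be reached without overlap."""

    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"could not reach gap fraction {target:.3f} without overlap; "
            f"achieved {achieved:.3f}"
        )
        self.target = target
        self.achieved = achieved


@dataclass
class GapCatalogue:
    """Empirical distribution of gap (length, start slot) pairs.

    ``lengths`` in half hours (1..144), ``start_slots`` as half-hour-of-day
    indices (0..47); entries are aligned pairs.
    """

    lengths: np.ndarray
    start_slots: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.start_slots = np.asarray(self.start_slots, dtype=np.int64)
        if self.lengths.shape != self.start_slots.shape:
            raise ValueError("lengths and start_slots must align")
        if self.lengths.size:
            if self.lengths.min() < 1 or self.lengths.max() > MAX_GAP_LEN:
                raise ValueError(f"gap lengths must be in 1..{MAX_GAP_LEN}")
            if self.start_slots.min() < 0 or self.start_slots.max() >= RECORDS_PER_DAY:
                raise ValueError("start slots must be in 0..47")

    def __len__(self) -> int:
        return int(self.lengths.size)


@dataclass
class GapPlan:
    """Boolean mask of artificial gaps over one series.

    When produced by :func:`insert_gaps`, ``starts``/``lengths`` record the
    individual inserted gaps (abutting gaps stay distinguishable even
    though their mask runs merge).
    """

    mask: np.ndarray
    gap_fraction: float = float("nan")
    replicate_id: int = 0
    starts: np.ndarray | None = None
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.starts is not None:
            self.starts = np.asarray(self.starts, dtype=np.int64)
            self.lengths = np.asarray(self.lengths, dtype=np.int64)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def to_json(self) -> str:
        """Serialise as run-length encoded JSON."""
        runs = _runs(self.mask)
        return json.dumps(
            {
                "n": int(self.mask.size),
                "runs": [[int(s), int(l)] for s, l in runs],
                "gap_fraction": None
                if np.isnan(self.gap_fraction)
                else self.gap_fraction,
                "replicate_id": self.replicate_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GapPlan":
        obj = json.loads(text)
        mask = np.zeros(obj["n"], dtype=bool)
        for start, length in obj["runs"]:
            mask[start : start + length] = True
        frac = obj.get("gap_fraction")
        return cls(
            mask=mask,
            gap_fraction=float("nan") if frac is None else frac,
            replicate_id=obj.get("replicate_id", 0),
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def extract_catalogue(series: FluxSeries) -> GapCatalogue:
    """Catalogue the maximal missing-NEE runs of a series.

    Runs longer than three days are excluded: only gaps of 0.5 h to 3 days
    are ever re-inserted.  A gap-free series yields an empty catalogue.
    """
    slots = series.slot
    lengths, starts = [], []
    for start, length in _runs(series.missing):
        if length <= MAX_GAP_LEN:
            lengths.append(length)
            starts.append(int(slots[start]))
    return GapCatalogue(
        lengths=np.array(lengths, dtype=np.int64),
        start_slots=np.array(starts, dtype=np.int64),
        source="extracted",
    )


def default_catalogue(seed: int = 0, n_entries: int = 2000) -> GapCatalogue:
    """Synthetic gap catalogue for users with no real file.

    Emulates the gross features of tower records: start times weighted
    toward night (low-turbulence filtering), lengths with a geometric tail
    capped at three days plus a spike of single-half-hour gaps.
    """
    rng = np.random.default_rng(seed)
    # start-slot weights: night slots (roughly 18:00–06:00) three times
    # likelier than mid-day slots
    slots = np.arange(RECORDS_PER_DAY)
    w = 1.0 + 2.0 * ((slots < 12) | (slots >= 36))
    start_slots = rng.choice(slots, size=n_entries, p=w / w.sum())
    single = rng.random(n_entries) < 0.4
    geo = rng.geometric(p=0.12, size=n_entries)
    lengths = np.where(single, 1, np.clip(geo, 1, MAX_GAP_LEN))
    return GapCatalogue(lengths=lengths, start_slots=start_slots, source="synthetic")


def insert_gaps(
    series: FluxSeries,
    catalogue: GapCatalogue,
    gap_fraction: float,
    seed: int,
    replicate_id: int = 0,
    max_rejections: int = 200_000,
) -> GapPlan:
    """Insert non-overlapping artificial gaps drawn from a catalogue.

    Catalogue entries are drawn with replacement; each drawn gap is placed
    on a uniformly chosen day at its retained start slot, rejected if it
    would overlap an already placed gap, extend past the series end or
    cover a record that is not measured.  Drawing stops once the masked
    fraction reaches ``gap_fraction`` (overshoot bounded by one gap
    length).
    """
    if len(catalogue) == 0:
        raise ValueError("catalogue is empty")
    if not 0.0 < gap_fraction < 1.0:
        raise ValueError("gap_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(series)
    n_days = n // RECORDS_PER_DAY
    measured = series.measured
    mask = np.zeros(n, dtype=bool)
    target = int(np.ceil(gap_fraction * n))
    masked = 0
    rejections = 0
    starts, lengths = [], []
    while masked < target:
        if rejections > max_rejections:
            raise GapPlacementError(gap_fraction, masked / n)
        e = int(rng.integers(0, len(catalogue)))
        day = int(rng.integers(0, n_days))
        start = day * RECORDS_PER_DAY + int(catalogue.start_slots[e])
        stop = start + int(catalogue.lengths[e])
        if stop > n or mask[start:stop].any() or not measured[start:stop].all():
            rejections += 1
            continue
        mask[start:stop] = True
        starts.append(start)
        lengths.append(stop - start)
        masked = int(mask.sum())
    return GapPlan(
        mask=mask,
        gap_fraction=gap_fraction,
        replicate_id=replicate_id,
        starts=np.array(starts, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
    )


def label_evaluation_gaps(series: FluxSeries, scheme: str, seed: int = 0):
    """Exhaustive artificial-gap labellings for method evaluation.

    ``scheme='loo'`` yields one single-record plan per measured record
    (lazy generator — a full year produces ~17k plans).  ``scheme=
    'percent_folds'`` returns a list of 100 disjoint random folds, each
    masking ~1 % of the measured records, whose union is exactly the
    measured set.
    """
    measured_idx = np.flatnonzero(series.measured)
    n = len(series)
    if scheme == "loo":

        def _loo():
            for rep, i in enumerate(measured_idx):
                mask = np.zeros(n, dtype=bool)
                mask[i] = True
                yield GapPlan(mask=mask, replicate_id=rep)

        return _loo()
    if scheme == "percent_folds":
        if measured_idx.size < 100:
            raise ValueError("percent_folds needs >= 100 measured records")
        rng = np.random.default_rng(seed)
        order = rng.permutation(measured_idx)
        plans = []
        for rep, fold in enumerate(np.array_split(order, 100)):
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            plans.append(GapPlan(mask=mask, replicate_id=rep))
        return plans
    raise ValueError(f"unknown scheme '{scheme}' (use 'loo' or 'percent_folds')")
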