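"""Gradient-boosted-tree gap-filling with cyclic time features.

Boosted regression trees regress NEE on the readily available drivers
(SWR, air temperature, VPD).  Because the trees see no time axis, the
feature set is augmented with two cyclic encodings — of month and of time
of day — and a linear time index, which lets the model absorb the slow
temporal correlations that lookup-table methods handle with a moving
window:

    t1 = sin((month − 1)·2π/12)      t2 = cos((month − 1)·2π/12)
    t3 = sin(hour·2π/24)             t4 = cos(hour·2π/24)
    t5 = i   (half hours since the start of the year)

Hyperparameters are selected by per-dataset grid search followed by
taking the mode of each winning value across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from xgboost import XGBRegressor

from .gaps import GapPlan
from .mds import FillResult, MEASURED
from .series import FluxSeries


def time_features(month, hour, half_hour_index):
    """Cyclic month/time-of-day encodings plus the linear time index.

    ``month`` 1–12, ``hour`` decimal hour of day in [0, 24), and the
    running half-hour index from the start of the year.  Returns
    ``(t1, t2, t3, t4, t5)``.
    """
    month = np.asarray(month)
    hour = np.asarray(hour, dtype=float)
    if np.any(month < 1) or np.any(month > 12):
        raise ValueError("month must be in 1..12")
    if np.any(hour < 0) or np.any(hour >= 24):
        raise ValueError("hour must be in [0, 24)")
    ang_m = (month - 1) * 2.0 * np.pi / 12.0
    ang_h = hour * 2.0 * np.pi / 24.0
    return (
        np.sin(ang_m),
        np.cos(ang_m),
        np.sin(ang_h),
        np.cos(ang_h),
        np.asarray(half_hour_index),
    )


def feature_matrix(series: FluxSeries) -> np.ndarray:
    """(n, 8) driver + time-feature matrix: swr, tair, vpd, t1..t5."""
    hour = (series.time.hour + series.time.minute / 60.0).to_numpy()
    t1, t2, t3, t4, t5 = time_features(series.month, hour, np.arange(len(series)))
    return np.column_stack(
        [series.swr, series.tair, series.vpd, t1, t2, t3, t4, t5]
    ).astype(float)


@dataclass
class GBParams:
    """One concrete hyperparameter combination."""

    colsample: float = 1.0
    max_depth: int = 5
    min_samples: int = 5  # minimum observations to create a new node
    subsample: float = 1.0
    learning_rate: float = 0.1
    n_rounds: int = 200

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GBParams":
        return cls(**json.loads(text))


@dataclass
class GBConfig:
    """Hyperparameter search grids and fixed training settings."""

    colsample_grid: tuple = (0.4, 0.6, 0.8, 1.0)
    max_depth_grid: tuple = (3, 5, 10, 15)
    min_samples_grid: tuple = (2, 5, 10)
    subsample_grid: tuple = (0.65, 0.75, 1.0)
    learning_rate: float = 0.1
    n_rounds: int = 200
    holdout_fraction: float = 0.25  # validation split within each dataset


def _make_model(params: GBParams, seed: int) -> XGBRegressor:
    # squared-error loss: the hessian is 1 per observation, so
    # min_child_weight equals the minimum observations per new node
    return XGBRegressor(
        n_estimators=params.n_rounds,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        colsample_bytree=params.colsample,
        subsample=params.subsample,
        min_child_weight=params.min_samples,
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def _grid(config: GBConfig):
    for cs in config.colsample_grid:
        for md in config.max_depth_grid:
            for ms in config.min_samples_grid:
                for ss in config.subsample_grid:
                    yield GBParams(
                        colsample=cs,
                        max_depth=md,
                        min_samples=ms,
                        subsample=ss,
                        learning_rate=config.learning_rate,
                        n_rounds=config.n_rounds,
                    )


def _mode_smallest(values):
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return vals[counts == counts.max()].min()


def select_hyperparameters(
    datasets, config: GBConfig | None = None, seed: int = 0
) -> GBParams:
    """Grid search per dataset, then the mode of each hyperparameter.

    Each dataset's measured records are split into a training part and a
    random holdout; the full grid is scored by holdout squared error and
    the per-dataset winner recorded.  The returned combination takes, for
    each hyperparameter separately, the most frequent winning value across
    datasets (ties resolved toward the smaller value).  Datasets with a
    constant target are skipped with a warning.
    """
    config = config or GBConfig()
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    rng = np.random.default_rng(seed)
    winners: list[GBParams] = []
    for series in datasets:
        meas = np.flatnonzero(series.measured)
        y_all = series.nee[meas]
        if np.all(y_all == y_all[0]):
            warnings.warn("skipping degenerate dataset with constant NEE")
            continue
        x = feature_matrix(series)
        hold = rng.random(meas.size) < config.holdout_fraction
        tr, va = meas[~hold], meas[hold]
        best, best_err = None, np.inf
        for params in _grid(config):
            model = _make_model(params, seed)
            model.fit(x[tr], series.nee[tr])
            err = float(np.mean((model.predict(x[va]) - series.nee[va]) ** 2))
            if err < best_err:
                best, best_err = params, err
        winners.append(best)
    if not winners:
        raise ValueError("all datasets were degenerate")
    return GBParams(
        colsample=float(_mode_smallest([w.colsample for w in winners])),
        max_depth=int(_mode_smallest([w.max_depth for w in winners])),
        min_samples=int(_mode_smallest([w.min_samples for w in winners])),
        subsample=float(_mode_smallest([w.subsample for w in winners])),
        learning_rate=config.learning_rate,
        n_rounds=config.n_rounds,
    )


def fit_and_fill(
    series: FluxSeries,
    plan: GapPlan,
    params: GBParams | None = None,
    seed: int = 0,
    min_train: int = 500,
) -> FillResult:
    """Train on unmasked measured records, predict at masked records.

    The model never sees a masked record's NEE; features with missing
    drivers are handled natively by the tree learner.  Reproducible for a
    fixed seed and parameter set.
    """
    params = params or GBParams()
    mask = plan.mask
    if mask.size != len(series):
        raise ValueError("plan mask length does not match series")
    train = series.measured & ~mask
    n_train = int(train.sum())
    if n_train < min_train:
        raise ValueError(f"need >= {min_train} training records, have {n_train}")
    nee_out = series.nee.copy()
    step_out = np.full(len(series), MEASURED, dtype=np.int64)
    size_out = np.zeros(len(series), dtype=np.int64)
    targets = np.flatnonzero(mask)
    if targets.size:
        x = feature_matrix(series)
        model = _make_model(params, seed)
        model.fit(x[train], series.nee[train])
        nee_out[targets] = model.predict(x[targets])
        step_out[targets] = 0
        size_out[targets] = n_train
    return FillResult(
        nee_filled=nee_out,
        fill_step=step_out,
        sample_size=size_out,
        mask=mask.copy(),
        config=params,
    )
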