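"""Neural-network surrogate of the NEE generating process.

For users with real tower files: fit a smooth regressor
``NEE = f(tair, tsoil, swr, vpd)`` to all measured records, then use it as
the truth function of a synthetic year.  The network is a small sequential
model — four hidden layers of 16, 32, 32 and 32 units with activations
linear, tanh, tanh and relu, and a linear output — trained with Adam on a
mean-squared-error loss.  Implemented directly on numpy; inputs and the
target are standardised internally.

Training hyperparameters (epochs, batch size, learning rate) are package
defaults chosen to recover smooth generating functions reliably; they are
exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import FluxSeries

_LAYER_SIZES = (16, 32, 32, 32)
_ACTIVATIONS = ("identity", "tanh", "tanh", "relu")


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "identity":
        return x
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(name)


def _act_grad(name: str, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    if name == "identity":
        return np.ones_like(pre)
    if name == "tanh":
        return 1.0 - post**2
    if name == "relu":
        return (pre > 0).astype(float)
    raise ValueError(name)


@dataclass
class SurrogateModel:
    """Trained NEE surrogate; call :meth:`predict` with driver arrays."""

    weights: list
    biases: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    def predict(self, tair, tsoil, swr, vpd) -> np.ndarray:
        x = np.column_stack(
            [np.asarray(v, dtype=float) for v in (tair, tsoil, swr, vpd)]
        )
        h = (x - self.x_mean) / self.x_sd
        for w, b, act in zip(self.weights[:-1], self.biases[:-1], _ACTIVATIONS):
            h = _act(act, h @ w + b)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[:, 0] * self.y_sd + self.y_mean

    def predict_series(self, series: FluxSeries) -> np.ndarray:
        if series.tsoil is None:
            raise ValueError("surrogate prediction requires tsoil")
        return self.predict(series.tair, series.tsoil, series.swr, series.vpd)


def fit_truth_surrogate(
    measured: FluxSeries,
    epochs: int = 300,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    seed: int = 0,
    min_records: int = 1000,
) -> SurrogateModel:
    """Fit the surrogate network to all measured records of a series.

    Requires at least ``min_records`` measured half hours spanning both
    day and night, and a soil-temperature driver.
    """
    if measured.tsoil is None:
        raise ValueError("surrogate training requires a tsoil driver")
    mask = (
        measured.measured
        & np.isfinite(measured.swr)
        & np.isfinite(measured.tair)
        & np.isfinite(measured.vpd)
        & np.isfinite(measured.tsoil)
    )
    n = int(mask.sum())
    if n < min_records:
        raise ValueError(f"need >= {min_records} measured records, have {n}")
    swr = measured.swr[mask]
    if not (np.any(swr <= 20.0) and np.any(swr > 20.0)):
        raise ValueError("training data must span both day and night")

    x = np.column_stack(
        [measured.tair[mask], measured.tsoil[mask], swr, measured.vpd[mask]]
    )
    y = measured.nee[mask]
    x_mean, x_sd = x.mean(axis=0), x.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
    xs = (x - x_mean) / x_sd
    ys = ((y - y_mean) / y_sd)[:, None]

    rng = np.random.default_rng(seed)
    sizes = (x.shape[1], *_LAYER_SIZES, 1)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(s) for s in sizes[1:]]

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = xs[idx], ys[idx]
            # forward
            pres, posts = [], [xb]
            h = xb
            for w, b, act in zip(weights[:-1], biases[:-1], _ACTIVATIONS):
                pre = h @ w + b
                h = _act(act, pre)
                pres.append(pre)
                posts.append(h)
            out = h @ weights[-1] + biases[-1]
            # backward (MSE)
            delta = 2.0 * (out - yb) / len(idx)
            grads_w = [None] * len(weights)
            grads_b = [None] * len(weights)
            grads_w[-1] = posts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            for li in range(len(weights) - 2, -1, -1):
                delta = (delta @ weights[li + 1].T) * _act_grad(
                    _ACTIVATIONS[li], pres[li], posts[li + 1]
                )
                grads_w[li] = posts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
            # Adam update
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for li in range(len(weights)):
                mw[li] = beta1 * mw[li] + (1 - beta1) * grads_w[li]
                vw[li] = beta2 * vw[li] + (1 - beta2) * grads_w[li] ** 2
                weights[li] -= learning_rate * (mw[li] / corr1) / (
                    np.sqrt(vw[li] / corr2) + eps
                )
                mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                biases[li] -= learning_rate * (mb[li] / corr1) / (
                    np.sqrt(vb[li] / corr2) + eps
                )

    return SurrogateModel(
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )
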