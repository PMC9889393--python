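"""Fit the neural-network surrogate to 'measured' data.

For users with real tower files: the surrogate learns NEE as a smooth
function of air temperature, soil temperature, SWR and VPD, and then
serves as the truth model of fully synthetic test years.  Here it is
demonstrated on synthetic 'measurements' whose generating function is
known, so the recovery error is measurable.
"""

import numpy as np

import fluxgap as fg

# a driver-only truth (no day-of-year dependence) is exactly recoverable
truth = fg.TruthModel(season_start=-200.0, season_end=2000.0)
clean, _ = fg.make_synthetic_year(truth=truth, seed=3)

rng = np.random.default_rng(0)
holdout = rng.random(len(clean)) < 0.3
train = clean.copy()
train.nee[holdout] = np.nan
train.qc[holdout] = 1

model = fg.fit_truth_surrogate(train, epochs=150, learning_rate=3e-3, seed=0)
pred = model.predict_series(clean)
rmse = np.sqrt(np.mean((pred[holdout] - clean.nee[holdout]) ** 2))
print(f"holdout RMSE: {rmse:.3f} umol m-2 s-1")
print(f"NEE sd:       {np.std(clean.nee):.3f}")
print(f"ratio:        {rmse / np.std(clean.nee):.1%}")

# A ratio of a few percent means the network recovered the generating
# light-response/Q10 surface almost perfectly from one year of data.
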