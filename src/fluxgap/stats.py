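"""Statistical tests for replicate-level gap-filling errors.

Whether a set of replicate biases or balance errors differs from zero is
judged with the exact two-sided Wilcoxon signed-rank test, with a
Shapiro–Wilk normality screen reported alongside.  Pairwise method
comparisons use Conover's post-hoc test on Kruskal–Wallis ranks with
Holm-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class BiasTest:
    """Result of the median-different-from-zero test on replicates."""

    p_wilcoxon: float
    p_shapiro: float
    n: int
    warning: str | None = None


def test_bias_nonzero(per_replicate_values, min_n: int = 5) -> BiasTest:
    """Exact two-sided Wilcoxon signed-rank test for median ≠ 0.

    All-zero input returns p = 1 by convention (flagged); fewer than
    ``min_n`` replicates attaches an insufficient-power warning.
    """
    x = np.asarray(per_replicate_values, dtype=float)
    note = None
    if x.size < min_n:
        note = f"only {x.size} replicates; test has little power"
    if np.all(x == 0):
        return BiasTest(p_wilcoxon=1.0, p_shapiro=float("nan"), n=int(x.size),
                        warning=note or "all replicate values are exactly zero")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_w = float(sps.wilcoxon(x, alternative="two-sided", mode="exact").pvalue)
        p_s = float(sps.shapiro(x).pvalue) if x.size >= 3 else float("nan")
    return BiasTest(p_wilcoxon=p_w, p_shapiro=p_s, n=int(x.size), warning=note)


def conover_holm(per_method_errors: dict) -> pd.DataFrame:
    """Pairwise Conover tests across methods, Holm-adjusted.

    ``per_method_errors`` maps method name → replicate error values; all
    methods must have the same replicate count.  Returns a symmetric
    DataFrame of adjusted p-values (diagonal 1).

    The statistic follows the Conover–Iman procedure: all observations
    are ranked jointly, and each pair is compared with a t statistic
    built from the rank means, the pooled rank variance and the
    Kruskal–Wallis H of the full layout, on N − k degrees of freedom.
    """
    methods = list(per_method_errors)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    groups = [np.asarray(per_method_errors[m], dtype=float) for m in methods]
    sizes = {g.size for g in groups}
    if len(sizes) != 1:
        raise ValueError("methods must have equal replicate counts")
    k = len(groups)
    x = np.concatenate(groups)
    n_total = x.size
    ranks = sps.rankdata(x)
    bounds = np.cumsum([0] + [g.size for g in groups])
    rank_groups = [ranks[bounds[i] : bounds[i + 1]] for i in range(k)]
    rbar = np.array([rg.mean() for rg in rank_groups])
    ns = np.array([rg.size for rg in rank_groups])

    # Kruskal–Wallis H with tie correction
    h = float(sps.kruskal(*groups).statistic) if np.unique(x).size > 1 else 0.0
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    factor = s2 * (n_total - 1 - h) / (n_total - k)
    factor = max(factor, 1e-300)

    raw = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        se = np.sqrt(factor * (1.0 / ns[i] + 1.0 / ns[j]))
        t = (rbar[i] - rbar[j]) / se
        raw.append(2.0 * sps.t.sf(abs(t), df=n_total - k))
    adjusted = multipletests(raw, method="holm")[1]

    out = pd.DataFrame(np.ones((k, k)), index=methods, columns=methods)
    for (i, j), p in zip(pairs, adjusted):
        out.iloc[i, j] = out.iloc[j, i] = p
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
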