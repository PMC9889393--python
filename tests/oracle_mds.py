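"""Independent brute-force MDS reference implementation.

Deliberately naive: for every gap it scans the whole record list and
applies the window and tolerance predicates literally, walking the same
cascade schedule.  Used only to cross-check the production kernel;
shares no code with it.
"""

import math


def _tolerance(cfg, tswr):
    return cfg.swr_tol_low if tswr <= cfg.swr_breakpoint else cfg.swr_tol_high


def _slot_distance(a, b):
    d = abs(a - b)
    return min(d, 48 - d)


def brute_force_fill(series, mask, cfg):
    """Fill every masked record; returns list of (index, value, step).

    value is NaN and step is None when the cascade fails.
    """
    n = len(series)
    nee = series.nee
    swr = series.swr
    tair = series.tair
    vpd = series.vpd
    slot = series.slot
    measured = series.measured
    results = []
    for g in range(n):
        if not mask[g]:
            continue
        tswr, ttair, tvpd = swr[g], tair[g], vpd[g]
        have_swr = math.isfinite(tswr)
        have_all = (
            have_swr and math.isfinite(ttair) and math.isfinite(tvpd)
        )
        tol = _tolerance(cfg, tswr) if have_swr else None
        value, step_found = float("nan"), None
        for si, (kind, hw) in enumerate(cfg.window_schedule):
            if kind in (0, 1) and not have_swr:
                continue
            if kind == 0 and not have_all:
                continue
            picked = []
            for j in range(n):
                if j == g or not measured[j] or mask[j]:
                    continue
                if kind == 2:
                    if abs(j - g) > hw * 48 + 2:
                        continue
                    if _slot_distance(slot[j], slot[g]) > 2:
                        continue
                else:
                    if abs(j - g) > hw * 48:
                        continue
                    if not abs(swr[j] - tswr) <= tol:
                        continue
                    if kind == 0:
                        if not abs(tair[j] - ttair) <= cfg.tair_tol:
                            continue
                        if not abs(vpd[j] - tvpd) <= cfg.vpd_tol:
                            continue
                picked.append(j)
            if len(picked) >= cfg.min_sample:
                if (
                    cfg.variant == "subsample_mean"
                    and kind != 2
                    and tswr >= cfg.day_swr_min
                ):
                    lo = [nee[j] for j in picked if swr[j] < tswr]
                    hi = [nee[j] for j in picked if swr[j] > tswr]
                    if lo and hi:
                        value = 0.5 * (
                            sum(lo) / len(lo) + sum(hi) / len(hi)
                        )
                    else:
                        value = sum(nee[j] for j in picked) / len(picked)
                else:
                    value = sum(nee[j] for j in picked) / len(picked)
                step_found = si
                break
        results.append((g, value, step_found))
    return results
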