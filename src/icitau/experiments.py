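"""Canned simulation experiments built on the generators.

Each function runs one complete study — generate, apply missingness, measure
— and returns plain dicts/DataFrames, so the same code backs the example
scripts, the validation suite and the reproduction script.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import ici_kt
from .matrix import correlate_all
from . import simulate as sim

__all__ = ["sorted_pair_missingness_sweep", "noisy_pair_censoring_sweep",
           "dynamic_range_comparison", "runtime_complexity_fit"]


def _pairwise_complete_pearson(x: np.ndarray, y: np.ndarray) -> float:
    keep = ~(np.isnan(x) | np.isnan(y))
    return float(pearsonr(x[keep], y[keep]).statistic)


def sorted_pair_missingness_sweep(n: int = 1000, max_missing: int = 499,
                                  step: int = 1, seed=None) -> dict:
    """Low-end missingness on perfectly rank-correlated pairs.

    For both orientations and missing counts 0..max_missing, plants that
    many missing values among the lowest ``max_missing`` values of one
    sample and records ICI-Kt and pairwise-complete Pearson.  Pearson is
    evaluated on the log intensities, where the sorted pair is exactly
    linear (+1 / -1) before any censoring, so its changes isolate the effect
    of the dropped points.  Returns the per-level table and the maximum
    absolute deviations of each statistic from its no-missing value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for direction, ref in (("positive", 1.0), ("negative", -1.0)):
        base = rng.lognormal(1.0, 0.5, size=n)
        x0, y0 = sim.sorted_pair(n=n, direction=direction, n_missing=0,
                                 pool=max_missing, base=base, seed=rng)
        pearson0 = _pairwise_complete_pearson(np.log(x0), np.log(y0))
        for n_missing in range(0, max_missing + 1, step):
            x, y = sim.sorted_pair(n=n, direction=direction,
                                   n_missing=n_missing, pool=max_missing,
                                   base=base, seed=rng)
            tau = ici_kt(x, y).tau
            pear = _pairwise_complete_pearson(np.log(x), np.log(y))
            rows.append({"direction": direction, "n_missing": n_missing,
                         "ici_kt": tau, "ici_kt_deviation": abs(tau - ref),
                         "pearson_log": pear,
                         "pearson_change": abs(pear - pearson0)})
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "tau_no_missing": {
            "positive": float(table.query(
                "direction == 'positive' and n_missing == 0")["ici_kt"].iloc[0]),
            "negative": float(table.query(
                "direction == 'negative' and n_missing == 0")["ici_kt"].iloc[0]),
        },
        "max_ici_deviation": float(table["ici_kt_deviation"].max()),
        "max_pearson_change": float(table["pearson_change"].max()),
    }


def noisy_pair_censoring_sweep(n: int = 1000, cutoffs=None, random_levels=None,
                               n_replicates: int = 100, seed=None) -> dict:
    """Left-censoring vs random missingness on the noisy replicate pair.

    Applies the intensity-cutoff grid (default 0..1.5 by 0.1) and the
    random-cell grid (default 0..300 by 50, ``n_replicates`` replicates per
    level) to one noisy pair, recording ICI-Kt and pairwise-complete Pearson
    at every condition.  Random-level statistics are replicate averages.
    """
    cutoffs = np.arange(0, 1.51, 0.1) if cutoffs is None else np.asarray(cutoffs)
    random_levels = (np.arange(0, 301, 50) if random_levels is None
                     else np.asarray(random_levels))
    rng = np.random.default_rng(seed)
    x, y = sim.noisy_pair(n=n, seed=rng)
    rows = []
    for c in cutoffs:
        xc, yc = sim.inject_missing(x, y, "cutoff", c)
        rows.append({"scheme": "cutoff", "level": float(c),
                     "ici_kt": ici_kt(xc, yc).tau,
                     "pearson_complete": _pairwise_complete_pearson(xc, yc)})
    for lev in random_levels:
        taus, pears = [], []
        for _ in range(n_replicates):
            xr, yr = sim.inject_missing(x, y, "random", int(lev), seed=rng)
            taus.append(ici_kt(xr, yr).tau)
            pears.append(_pairwise_complete_pearson(xr, yr))
        rows.append({"scheme": "random", "level": float(lev),
                     "ici_kt": float(np.mean(taus)),
                     "pearson_complete": float(np.mean(pears))})
    table = pd.DataFrame(rows)
    start = float(table.query("scheme == 'cutoff' and level == 0")["ici_kt"].iloc[0])
    return {
        "table": table,
        "start_tau": start,
        "pearson_range": float(table["pearson_complete"].max()
                               - table["pearson_complete"].min()),
        "cutoff_tau_trend": table.query("scheme == 'cutoff'")["ici_kt"].to_numpy(),
        "random_tau_trend": table.query("scheme == 'random'")["ici_kt"].to_numpy(),
    }


def dynamic_range_comparison(n_features: int = 1000, n_samples: int = 100,
                             censor_max: float = 1.5, seed=None,
                             cores: int = 1) -> dict:
    """Reference-vs-trimmed correlation error: ICI-Kt against half-minimum-
    imputed Pearson, under per-sample dynamic-range censoring.

    Returns the per-pair error table and, over pairs whose larger missing
    count stays below half the features, the fraction where ICI-Kt is closer
    to its reference value than imputed Pearson is to its own.
    """
    import warnings
    reference, trimmed = sim.dynamic_range_dataset(
        n_features=n_features, n_samples=n_samples, censor_max=censor_max,
        seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ik_ref = correlate_all(reference, "IK", cores=cores)
        ik_trim = correlate_all(trimmed, "IK", cores=cores)
    imputed = sim.half_min_impute(trimmed)
    p_ref = reference.to_dataframe().corr().to_numpy()
    p_trim = imputed.to_dataframe().corr().to_numpy()
    n_missing = np.isnan(trimmed.values).sum(axis=0)
    iu = np.triu_indices(n_samples, k=1)
    err_ik = np.abs(ik_ref.tau.to_numpy() - ik_trim.tau.to_numpy())[iu]
    err_pi = np.abs(p_ref - p_trim)[iu]
    max_missing = np.maximum(n_missing[iu[0]], n_missing[iu[1]])
    table = pd.DataFrame({"sample_a": iu[0], "sample_b": iu[1],
                          "max_missing": max_missing,
                          "ici_kt_error": err_ik, "pearson_imputed_error": err_pi})
    usable = max_missing < n_features / 2
    frac = float(np.mean(err_ik[usable] < err_pi[usable])) if usable.any() else np.nan
    return {"table": table, "n_usable_pairs": int(usable.sum()),
            "fraction_ici_closer": frac}


def runtime_complexity_fit(sizes=(100, 250, 500, 1000, 2000, 3500, 5000),
                           target_seconds: float = 0.05, n_timings: int = 5,
                           seed=None) -> dict:
    """Empirical scaling of the fast path: n log n versus n^2 regression.

    Times :func:`ici_kt` at each size (best of ``n_timings`` repetition
    batches), then least-squares-fits time against a + b*f(n) for
    f = n log n and f = n^2, comparing residual sums of squares.
    """
    rng = np.random.default_rng(seed)
    ici_kt(rng.normal(size=64), rng.normal(size=64))  # trigger jit compile
    times = []
    for n in sizes:
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        reps = max(3, int(target_seconds / max(1e-6, n * 3e-7)))
        best = np.inf
        for _ in range(n_timings):
            t0 = time.perf_counter()
            for _ in range(reps):
                ici_kt(x, y)
            best = min(best, (time.perf_counter() - t0) / reps)
        times.append(best)
    t = np.asarray(times)
    ns = np.asarray(sizes, dtype=float)

    def rss(f):
        design = np.column_stack([np.ones_like(ns), f(ns)])
        beta, *_ = np.linalg.lstsq(design, t, rcond=None)
        return float(np.sum((t - design @ beta) ** 2))

    r_nlogn = rss(lambda v: v * np.log(v))
    r_n2 = rss(lambda v: v ** 2)
    return {"sizes": list(sizes), "seconds": times,
            "rss_nlogn": r_nlogn, "rss_n2": r_n2,
            "nlogn_fits_better": r_nlogn < r_n2}
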