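"""Is the missingness left-censoring?  Two diagnostics.

If values go missing because they fall below a detection limit, a feature
that is missing from many samples should sit low in the intensity ranking of
the samples where it *is* seen, and the observed values of partially-missing
features should lie mostly below their sample medians.  The first idea gives
the median-rank-vs-missingness profile; the second gives an exact binomial
test against a null success ratio of 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, binomtest, rankdata

from .matrix import OmicsMatrix

__all__ = ["RankProfile", "BinomialCensorResult",
           "median_rank_profile", "left_censorship_test"]


@dataclass
class RankProfile:
    """Per-group median-rank profile.

    ``features``: one row per profiled feature — median_rank (median over
    the samples where the feature is present; rank 1 = lowest value in a
    sample, ties get average ranks) and n_missing (samples of the group the
    feature is absent from).  ``by_n_missing``: per missingness level, the
    median and minimum of the feature median ranks.
    """

    group: str
    features: pd.DataFrame
    by_n_missing: pd.DataFrame


def _group_iter(data: OmicsMatrix, groups) -> list[tuple[str, np.ndarray]]:
    labels = pd.Series(groups if groups is not None else data.groups)
    if labels.empty or labels.isna().any():
        raise ValueError("every sample needs a group label")
    labels = labels.loc[data.sample_ids]
    return [(str(g), (labels == g).to_numpy()) for g in labels.unique()]


def median_rank_profile(data: OmicsMatrix, groups=None) -> dict[str, RankProfile]:
    """Median rank of each feature vs how many samples it is missing from.

    Under left-censoring the median-of-median-ranks decreases as n_missing
    grows, and the minimum median rank shows a floor below which features
    with few missing values never fall.
    """
    out: dict[str, RankProfile] = {}
    for gname, sel in _group_iter(data, groups):
        vals = data.values[:, sel]
        present = ~np.isnan(vals)
        ranks = np.full_like(vals, np.nan)
        for s in range(vals.shape[1]):
            p = present[:, s]
            ranks[p, s] = rankdata(vals[p, s], method="average")
        n_present = present.sum(axis=1)
        profiled = n_present > 0
        dropped = int((~profiled).sum())
        if dropped:
            warnings.warn(f"group {gname!r}: {dropped} features absent from "
                          "every sample were excluded from the profile")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(ranks[profiled], axis=1)
        feats = pd.DataFrame({
            "feature_id": [f for f, k in zip(data.feature_ids, profiled) if k],
            "median_rank": med,
            "n_missing": sel.sum() - n_present[profiled],
        }).set_index("feature_id")
        agg = (feats.groupby("n_missing")["median_rank"]
               .agg(median_of_median_ranks="median", min_of_median_ranks="min"))
        out[gname] = RankProfile(gname, feats, agg)
    return out


@dataclass
class BinomialCensorResult:
    """Exact binomial test of below-sample-median incidence.

    ``estimate`` near 1 says the observed values of partially-missing
    features sit below their sample medians — the left-censoring signature;
    near 0.5 says missingness looks random.  ``ci_lower`` is the one-sided
    95% exact (Clopper-Pearson) lower bound; ``p_value`` is the exact
    binomial probability of at least this many successes under p = 0.5.
    """

    trials: int
    successes: int
    estimate: float
    ci_lower: float
    p_value: float


def left_censorship_test(data: OmicsMatrix, groups=None) -> BinomialCensorResult:
    """Binomial left-censorship test aggregated across sample groups.

    Within each group: compute each sample's median over its present
    features; for every feature missing from at least one sample of the
    group, compare each of its present values to that sample's median.
    Strictly below the median counts as a success.  Successes and trials are
    pooled over groups and tested one-sided against 0.5.
    """
    successes = trials = 0
    for _, sel in _group_iter(data, groups):
        vals = data.values[:, sel]
        present = ~np.isnan(vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sample_medians = np.nanmedian(vals, axis=0)
        partially_missing = ~present.all(axis=1)
        v = vals[partially_missing]
        p = present[partially_missing]
        below = (v < sample_medians[None, :]) & p
        trials += int(p.sum())
        successes += int(below.sum())
    if trials == 0:
        raise ValueError("no partially-missing features: nothing to test")
    test = binomtest(successes, trials, p=0.5, alternative="greater")
    if successes == 0:
        ci_lower = 0.0
    else:
        ci_lower = float(beta.ppf(0.05, successes, trials - successes + 1))
    return BinomialCensorResult(trials=trials, successes=successes,
                                estimate=successes / trials,
                                ci_lower=ci_lower, p_value=float(test.pvalue))
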