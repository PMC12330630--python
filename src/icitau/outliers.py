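"""Outlier-sample QC from a sample-sample correlation matrix.

A sample that correlates poorly with its own treatment group is suspect.
Each sample gets the median of its within-group correlations, transformed to
a score log(1 - cor_median) so that poor samples sit at the *high* end; the
flagging rule is the Tukey boxplot fence (upper hinge + 1.5 x hinge spread)
computed over the pooled score distribution, and only the high end is ever
flagged — unusually *good* samples are not outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import (CorrelationMatrices, OmicsMatrix, correlate_all,
                     filter_by_presence)

MAD_CONSTANT = 1.4826  # consistency with the normal sd

__all__ = ["OutlierReport", "GroupSpread", "median_group_correlations",
           "detect_outliers", "presence_filtered_run", "group_spread",
           "tukey_fivenum", "plot_outliers"]


@dataclass
class OutlierReport:
    """Per-sample table: group, median_correlation, score, is_outlier."""

    samples: pd.DataFrame
    method: str = ""
    presence_fraction: float | None = None

    @property
    def outliers(self) -> list[str]:
        return list(self.samples.index[self.samples["is_outlier"]])


@dataclass
class GroupSpread:
    """Median and MAD of sample median correlations per group and cutoff,
    plus all pairwise between-group differences of both."""

    per_group: pd.DataFrame
    differences: pd.DataFrame


def _align_groups(index, groups) -> pd.Series:
    labels = pd.Series(groups)
    missing = set(index) - set(labels.index)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)}")
    return labels.loc[list(index)]


def median_group_correlations(mats: CorrelationMatrices | pd.DataFrame,
                              groups) -> pd.Series:
    """Median correlation of each sample to the other samples of its group.

    The self-correlation is excluded.  Raises on singleton groups, which
    have no within-group partner to correlate against.
    """
    cor = mats.tau if isinstance(mats, CorrelationMatrices) else mats
    labels = _align_groups(cor.index, groups)
    out = {}
    for g in labels.unique():
        members = list(labels.index[labels == g])
        if len(members) < 2:
            raise ValueError(f"group {g!r} has a single sample")
        sub = cor.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, np.nan)
        meds = np.nanmedian(sub, axis=1)
        out.update(dict(zip(members, meds)))
    return pd.Series(out, name="median_correlation").loc[cor.index]


def tukey_fivenum(x) -> tuple[float, float, float, float, float]:
    """Tukey five-number summary (min, lower hinge, median, upper hinge, max).

    Hinge positions follow the boxplot-statistics convention (depth
    floor((n+3)/2)/2), not interpolated quantiles.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n == 0:
        raise ValueError("empty input")
    n4 = math.floor((n + 3) / 2) / 2
    d = np.array([1.0, n4, (n + 1) / 2, n + 1 - n4, float(n)])
    lo = xs[np.floor(d).astype(int) - 1]
    hi = xs[np.ceil(d).astype(int) - 1]
    return tuple(0.5 * (lo + hi))


def detect_outliers(medians: pd.Series, groups, method: str = "",
                    presence_fraction: float | None = None) -> OutlierReport:
    """Flag samples whose score log(1 - median_correlation) exceeds the
    upper Tukey fence of the pooled score distribution.

    A median correlation of exactly 1 gives a score of -inf; such samples
    are kept in the report but can never be flagged and are left out of the
    hinge computation.  If every score is identical there are no outliers.
    """
    labels = _align_groups(medians.index, groups)
    with np.errstate(divide="ignore"):
        scores = np.log(1.0 - medians.to_numpy(dtype=float))
    finite = np.isfinite(scores)
    flagged = np.zeros(medians.size, dtype=bool)
    if finite.any():
        _, lower, _, upper, _ = tukey_fivenum(scores[finite])
        fence = upper + 1.5 * (upper - lower)
        flagged = finite & (scores > fence)
    report = pd.DataFrame({
        "group": labels.to_numpy(),
        "median_correlation": medians.to_numpy(dtype=float),
        "score": scores,
        "is_outlier": flagged,
    }, index=medians.index)
    return OutlierReport(report, method=method,
                         presence_fraction=presence_fraction)


def presence_filtered_run(data: OmicsMatrix, groups, fraction: float,
                          method: str = "IK", perspective: str = "global",
                          cores: int = 1) -> OutlierReport:
    """Filter features by within-group presence, recompute correlations, and
    re-flag outliers — the sensitivity sweep over presence cutoffs."""
    filtered = filter_by_presence(data, fraction, groups=pd.Series(groups))
    mats = correlate_all(filtered, method=method, axis="samples",
                         perspective=perspective, cores=cores)
    medians = median_group_correlations(mats, groups)
    return detect_outliers(medians, groups, method=method,
                           presence_fraction=fraction)


def group_spread(medians: Mapping[float, pd.Series] | pd.Series,
                 groups) -> GroupSpread:
    """Median and MAD of sample median correlations, per group and cutoff.

    ``medians`` maps presence cutoff -> per-sample median correlations (a
    bare Series is treated as a single cutoff of 0).  MAD uses the 1.4826
    normal-consistency constant.  Differences are reported for every ordered
    group pair at each cutoff.
    """
    if isinstance(medians, pd.Series):
        medians = {0.0: medians}
    rows, diffs = [], []
    for cutoff, med in medians.items():
        labels = _align_groups(med.index, groups)
        stats = {}
        for g in labels.unique():
            v = med[labels == g].to_numpy(dtype=float)
            m = float(np.median(v))
            mad = MAD_CONSTANT * float(np.median(np.abs(v - m)))
            stats[g] = (m, mad)
            rows.append({"cutoff": cutoff, "group": g, "median": m, "mad": mad})
        names = list(stats)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ga, gb = names[a], names[b]
                diffs.append({
                    "cutoff": cutoff, "group_a": ga, "group_b": gb,
                    "median_difference": stats[ga][0] - stats[gb][0],
                    "mad_difference": stats[ga][1] - stats[gb][1],
                })
    return GroupSpread(pd.DataFrame(rows), pd.DataFrame(diffs))


def plot_outliers(reports: Mapping[str, OutlierReport], path=None):
    """Strip plot of per-sample median correlations per method, outliers
    highlighted and connected across methods.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(reports)
    fig, ax = plt.subplots(figsize=(2 + 1.5 * len(methods), 4))
    any_outlier = sorted({s for r in reports.values() for s in r.outliers})
    for k, m in enumerate(methods):
        df = reports[m].samples
        ax.scatter([k] * len(df), df["median_correlation"],
                   c=np.where(df["is_outlier"], "red", "0.4"), s=14)
    for s in any_outlier:
        ys = [reports[m].samples.loc[s, "median_correlation"] for m in methods]
        ax.plot(range(len(methods)), ys, color="red", alpha=0.3, lw=0.8)
    ax.set_xticks(range(len(methods)), methods)
    ax.set_ylabel("median within-group correlation")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
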