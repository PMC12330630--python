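"""Information-content-informed Kendall-tau (ICI-Kt) for a single vector pair.

Classical Kendall-tau ignores missing values.  In omics intensity matrices
most missingness is left-censoring — the analyte fell below the limit of
detection — so "missing" carries rank information: it is below every observed
value.  ICI-Kt extends the concordant/discordant pair definitions so that a
missing entry compares as smaller than any observed one, folds
missing-vs-missing pairs into the tie counts of the tau-b denominator, and
reports two companion quantities:

* ``tau_max`` — the largest tau-b attainable given the tie structure of the
  pair, useful as a theoretical ceiling and a dataset-wide scaling factor;
* ``completeness`` — the fraction of features missing in neither vector.

Two perspectives are supported.  Under ``"global"`` co-missing entries stay
in the census as ties in both vectors, so every pair over the same feature
set sees the same number of comparisons; under ``"local"`` co-missing entries
are dropped before counting, which suits a two-sample-only comparison.

Missing values are encoded as NaN throughout.

The production path (:func:`ici_kt`) replaces missing entries with a sentinel
strictly below every observed value and runs an O(n log n) mergesort census;
:func:`count_pairs_bruteforce` enumerates the extended pair rules explicitly
and exists as the O(n^2) reference the fast path is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from ._kernel import pair_census

Perspective = Literal["local", "global"]

__all__ = [
    "PairCounts",
    "KtResult",
    "DegenerateInputError",
    "UndefinedCorrelationError",
    "count_pairs_bruteforce",
    "ici_kt",
    "tau_max",
    "completeness",
    "tau_from_counts",
]


class DegenerateInputError(ValueError):
    """Input too degenerate to census: n < 2 or an all-missing vector."""


class UndefinedCorrelationError(ValueError):
    """Tau denominator is zero (a vector entirely tied after imputation)."""

    def __init__(self, message: str, counts: "PairCounts | None" = None):
        super().__init__(message)
        self.counts = counts


@dataclass(frozen=True)
class PairCounts:
    """Census of all i<j index pairs of one vector comparison.

    ``n_xtie``/``n_ytie`` count pairs tied in that vector (observed
    duplicates and missing-vs-missing alike); ``n_commontie`` counts pairs
    tied in both vectors at once.
    """

    n_tot: int
    n_concordant: int
    n_discordant: int
    n_xtie: int
    n_ytie: int
    n_commontie: int

    def __post_init__(self):
        if min(self.n_tot, self.n_concordant, self.n_discordant,
               self.n_xtie, self.n_ytie, self.n_commontie) < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class KtResult:
    """ICI-Kt statistic and companions for one vector pair."""

    tau: float
    tau_max: float
    completeness: float
    perspective: str
    p_value: float | None = None
    counts: PairCounts | None = None


def _validate(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be one-dimensional")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DegenerateInputError("need at least two observations")
    return x, y


def _trim_local(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = ~(np.isnan(x) & np.isnan(y))
    return x[keep], y[keep]


def _check_effective(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 2:
        raise DegenerateInputError(
            "fewer than two index positions remain after dropping co-missing entries"
        )
    if np.isnan(x).all() or np.isnan(y).all():
        raise DegenerateInputError("a vector is entirely missing")


def _impute_sentinel(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN with one less than the smallest finite value of the pair.

    Any strictly smaller sentinel produces identical ranks; subtracting 1
    avoids floating-point adjacency to the true minimum.
    """
    finite = np.concatenate([x[~np.isnan(x)], y[~np.isnan(y)]])
    sentinel = finite.min() - 1.0
    return (np.where(np.isnan(x), sentinel, x),
            np.where(np.isnan(y), sentinel, y))


def count_pairs_bruteforce(x, y, perspective: Perspective = "global") -> PairCounts:
    """Classify every i<j pair by the extended concordance rules.

    A missing value compares as below every observed value: a pair is
    concordant when the x-ordering and y-ordering agree under that reading,
    discordant when they disagree, and tied in a vector when both entries are
    equal observed values or both are missing.  Quadratic; used as the
    reference oracle for :func:`ici_kt`.
    """
    x, y = _validate(x, y)
    if perspective == "local":
        x, y = _trim_local(x, y)
    elif perspective != "global":
        raise ValueError(f"unknown perspective: {perspective!r}")
    _check_effective(x, y)
    n = x.size
    mx = np.isnan(x)
    my = np.isnan(y)
    n_con = n_dis = n_xt = n_yt = n_ct = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            # ordering of each coordinate with missing below everything:
            # -1 if i-th below j-th, +1 if above, 0 if tied
            if mx[i] and mx[j]:
                ox = 0
            elif mx[i]:
                ox = -1
            elif mx[j]:
                ox = 1
            else:
                ox = 0 if x[i] == x[j] else (1 if x[i] > x[j] else -1)
            if my[i] and my[j]:
                oy = 0
            elif my[i]:
                oy = -1
            elif my[j]:
                oy = 1
            else:
                oy = 0 if y[i] == y[j] else (1 if y[i] > y[j] else -1)
            if ox == 0 or oy == 0:
                if ox == 0:
                    n_xt += 1
                if oy == 0:
                    n_yt += 1
                if ox == 0 and oy == 0:
                    n_ct += 1
            elif ox == oy:
                n_con += 1
            else:
                n_dis += 1
    return PairCounts(n * (n - 1) // 2, n_con, n_dis, n_xt, n_yt, n_ct)


def tau_from_counts(counts: PairCounts) -> tuple[float, float]:
    """(tau-b, tau_max) assembled from a pair census.

    tau-b = (nc - nd) / sqrt((n_tot - n_xtie)(n_tot - n_ytie));
    tau_max replaces nc - nd with its ceiling nc + nd =
    n_tot - n_xtie - n_ytie + n_commontie.
    """
    den = math.sqrt(float(counts.n_tot - counts.n_xtie)
                    * float(counts.n_tot - counts.n_ytie))
    if den == 0.0:
        raise UndefinedCorrelationError(
            "tau undefined: a vector is entirely tied", counts=counts)
    num_max = counts.n_tot - counts.n_xtie - counts.n_ytie + counts.n_commontie
    return ((counts.n_concordant - counts.n_discordant) / den, num_max / den)


def completeness(x, y, n_feat: int | None = None) -> float:
    """Fraction of the feature space missing in neither vector.

    ``n_feat`` defaults to the vector length; pass the dataset's full feature
    count when the pair was subset upstream.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if n_feat is None:
        n_feat = x.size
    if n_feat <= 0:
        raise DegenerateInputError("n_feat must be positive")
    n_union_missing = int((np.isnan(x) | np.isnan(y)).sum())
    return (n_feat - n_union_missing) / n_feat


def _p_value_normal(census: dict, n: int) -> float:
    """Two-sided p-value from the tie-corrected normal approximation."""
    cmd = (census["n_tot"] - census["n_xtie"] - census["n_ytie"]
           + census["n_commontie"] - 2 * census["n_discordant"])
    m = n * (n - 1)
    var = (m * (2.0 * n + 5) - census["x1"] - census["y1"]) / 18.0
    var += 2.0 * census["n_xtie"] * census["n_ytie"] / m
    if n > 2:
        var += census["x0"] * census["y0"] / (9.0 * m * (n - 2))
    if var <= 0:
        return 1.0
    z = cmd / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def ici_kt(x, y, perspective: Perspective = "global",
           n_feat: int | None = None, p_value: bool = False) -> KtResult:
    """ICI-Kt of two vectors with NaN missingness (fast mergesort path).

    Missing entries are replaced by a sentinel strictly below every observed
    value, after which the extended pair classification coincides with plain
    tau-b on the imputed vectors; the census then runs in O(n log n).
    Classification is identical to :func:`count_pairs_bruteforce`.

    Parameters
    ----------
    perspective : "global" drops nothing; "local" removes co-missing indices
        first.
    n_feat : feature-space size for the completeness fraction (defaults to
        the untrimmed vector length).
    p_value : also compute the two-sided tie-corrected normal-approximation
        p-value.

    Raises
    ------
    DegenerateInputError
        Fewer than two effective observations, or an all-missing vector.
    UndefinedCorrelationError
        A vector is entirely tied after imputation (zero denominator); the
        exception carries the :class:`PairCounts`.
    """
    x, y = _validate(x, y)
    comp = completeness(x, y, n_feat=n_feat)
    if perspective == "local":
        xe, ye = _trim_local(x, y)
    elif perspective == "global":
        xe, ye = x, y
    else:
        raise ValueError(f"unknown perspective: {perspective!r}")
    _check_effective(xe, ye)
    xi, yi = _impute_sentinel(xe, ye)
    census = pair_census(xi, yi)
    counts = PairCounts(census["n_tot"], census["n_concordant"],
                        census["n_discordant"], census["n_xtie"],
                        census["n_ytie"], census["n_commontie"])
    tau, tmax = tau_from_counts(counts)
    pv = _p_value_normal(census, xi.size) if p_value else None
    return KtResult(tau=tau, tau_max=tmax, completeness=comp,
                    perspective=perspective, p_value=pv, counts=counts)


def tau_max(x, y, perspective: Perspective = "global") -> float:
    """Theoretical maximum tau-b for a pair given its tie structure.

    (n_tot - n_xtie - n_ytie + n_commontie) /
    sqrt((n_tot - n_xtie)(n_tot - n_ytie)), always in (0, 1].
    """
    return ici_kt(x, y, perspective=perspective).tau_max
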