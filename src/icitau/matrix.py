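"""Omics matrix container and all-pairs correlation under the named methods.

The seven method codes follow the comparison vocabulary used throughout the
package:

======  ==============================================================
code    meaning
======  ==============================================================
IK      ICI-Kt with zeros treated as missing
IKC     IK scaled (multiplied) elementwise by pairwise completeness
Kt      classic Kendall tau-b, zeros as missing, pairwise-complete
PB      Pearson with missing replaced by zero (zeros kept)
PN0     Pearson with zeros as missing, pairwise-complete
PL1     Pearson on log(x + 1), missing as zero
PL      Pearson on log(x), non-finite results as missing, pairwise-complete
======  ==============================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import (DegenerateInputError, UndefinedCorrelationError, ici_kt,
                   tau_from_counts)
from ._kernel import pair_census
from . import core

METHODS = ("IK", "IKC", "Kt", "PB", "PN0", "PL1", "PL")

__all__ = ["OmicsMatrix", "CorrelationMatrices", "METHODS",
           "apply_missing_encoding", "correlate_all",
           "scale_by_dataset_taumax", "filter_by_presence"]


@dataclass
class OmicsMatrix:
    """Features x samples numeric matrix with NaN-encoded missingness.

    ``values`` is float64 with NaN at masked cells; ``groups`` optionally
    labels each sample; ``provenance`` records transformations such as the
    zero-to-missing conversion.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    groups: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = set(self.sample_ids) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")
            self.groups = self.groups.loc[self.sample_ids]

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups=None,
                       provenance: list[str] | None = None) -> "OmicsMatrix":
        """Build from a features-in-rows DataFrame (NaN = missing)."""
        return cls(df.to_numpy(dtype=np.float64), list(df.index.astype(str)),
                   list(df.columns.astype(str)), groups=groups,
                   provenance=list(provenance or []))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def zeros_to_missing(self) -> "OmicsMatrix":
        """Return a copy with exact zeros converted to missing."""
        vals = self.values.copy()
        n = int((vals == 0).sum())
        vals[vals == 0] = np.nan
        return replace(self, values=vals,
                       provenance=self.provenance + [f"zeros_to_missing:{n}"])


@dataclass
class CorrelationMatrices:
    """Square per-method matrices over one axis of an OmicsMatrix."""

    method: str
    tau: pd.DataFrame
    completeness: pd.DataFrame | None = None
    tau_max: pd.DataFrame | None = None
    perspective: str = "global"


def apply_missing_encoding(data: OmicsMatrix, method: str) -> OmicsMatrix:
    """Re-encode zeros/missing the way ``method`` expects.

    All methods start from the convention that a missing cell and a zero cell
    are interchangeable encodings of "not detected"; each method then picks
    its own representation (see the module table).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    vals = data.values.copy()
    prov = list(data.provenance)
    if method in ("IK", "IKC", "Kt", "PN0"):
        vals[vals == 0] = np.nan
        prov.append(f"encoding:{method}:zeros_to_missing")
    elif method == "PB":
        vals[np.isnan(vals)] = 0.0
        prov.append("encoding:PB:missing_to_zero")
    elif method == "PL1":
        vals[np.isnan(vals)] = 0.0
        _check_nonnegative(vals, data, "log(x+1)")
        vals = np.log1p(vals)
        prov.append("encoding:PL1:log1p")
    elif method == "PL":
        _check_nonnegative(vals, data, "log(x)")
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log(vals)
        vals[~np.isfinite(vals)] = np.nan
        prov.append("encoding:PL:log_nonfinite_to_missing")
    return replace(data, values=vals, provenance=prov)


def _check_nonnegative(vals, data: OmicsMatrix, what: str) -> None:
    bad = np.argwhere(vals < 0)
    if bad.size:
        cells = [f"({data.feature_ids[i]}, {data.sample_ids[j]})"
                 for i, j in bad[:5]]
        raise ValueError(
            f"negative values under {what} at {len(bad)} cells, e.g. {cells}")


def _completeness_matrix(mask: np.ndarray) -> np.ndarray:
    """Pairwise completeness from a features x vectors missingness mask."""
    n_feat = mask.shape[0]
    m = mask.astype(np.int64)
    common = m.T @ m
    per = m.sum(axis=0)
    union = per[:, None] + per[None, :] - common
    return (n_feat - union) / n_feat


def _kendall_cell(x, y, method, perspective):
    """One Kendall-family cell; NaN (with a warning) on degenerate vectors."""
    try:
        if method == "Kt":
            keep = ~(np.isnan(x) | np.isnan(y))
            xk, yk = x[keep], y[keep]
            if xk.size < 2:
                raise DegenerateInputError("fewer than two complete observations")
            c = pair_census(xk, yk)
            tau, _ = tau_from_counts(core.PairCounts(
                c["n_tot"], c["n_concordant"], c["n_discordant"],
                c["n_xtie"], c["n_ytie"], c["n_commontie"]))
            return tau, np.nan
        res = ici_kt(x, y, perspective=perspective)
        return res.tau, res.tau_max
    except (DegenerateInputError, UndefinedCorrelationError) as exc:
        warnings.warn(f"correlation cell undefined: {exc}", stacklevel=2)
        return np.nan, np.nan


def _kendall_chunk(vectors, pairs, method, perspective):
    return [(i, j, *_kendall_cell(vectors[:, i], vectors[:, j],
                                  method, perspective))
            for i, j in pairs]


def correlate_all(data: OmicsMatrix, method: str = "IK",
                  axis: str = "samples", perspective: str = "global",
                  cores: int = 1) -> CorrelationMatrices:
    """All-pairs correlation matrices along one axis under one method.

    The pair list is statically partitioned across ``cores`` joblib workers;
    results are assembled by pair index, so the output is independent of the
    worker count and evaluation order.  Cells whose vectors are undefined
    under the method (e.g. all-missing) become NaN with a warning.
    """
    encoded = apply_missing_encoding(data, method)
    if axis == "samples":
        vectors = encoded.values
        ids = encoded.sample_ids
    elif axis == "features":
        vectors = encoded.values.T
        ids = encoded.feature_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    p = len(ids)
    if p < 2:
        raise ValueError("need at least two vectors to correlate")

    comp = pd.DataFrame(_completeness_matrix(np.isnan(vectors)),
                        index=ids, columns=ids)

    if method in ("PB", "PN0", "PL1", "PL"):
        # pandas corr is pairwise-complete over NaN by construction
        tau = pd.DataFrame(vectors, columns=ids).corr(method="pearson")
        np.fill_diagonal(tau.values, 1.0)
        return CorrelationMatrices(method, tau, completeness=comp,
                                   perspective=perspective)

    pairs = [(i, j) for i in range(p - 1) for j in range(i + 1, p)]
    chunks = np.array_split(np.arange(len(pairs)), max(1, min(cores, len(pairs))))
    results = Parallel(n_jobs=cores)(
        delayed(_kendall_chunk)(vectors, [pairs[k] for k in chunk],
                                method, perspective)
        for chunk in chunks if len(chunk))
    tau = np.eye(p)
    tmax = np.eye(p)
    for chunk in results:
        for i, j, t, tm in chunk:
            tau[i, j] = tau[j, i] = t
            tmax[i, j] = tmax[j, i] = tm
    tau = pd.DataFrame(tau, index=ids, columns=ids)
    tmax_df = None if method == "Kt" else pd.DataFrame(tmax, index=ids, columns=ids)
    if method == "IKC":
        tau = tau * comp
    return CorrelationMatrices(method, tau, completeness=comp,
                               tau_max=tmax_df, perspective=perspective)


def scale_by_dataset_taumax(mats: CorrelationMatrices) -> CorrelationMatrices:
    """Divide every tau by the dataset-wide maximum off-diagonal tau_max.

    One factor applied equally, so the theoretically best-off pair can reach
    1; sign and ordering of all correlations are preserved.
    """
    if mats.tau_max is None:
        raise ValueError("tau_max matrix required for dataset-wide scaling")
    tm = mats.tau_max.to_numpy().copy()
    np.fill_diagonal(tm, np.nan)
    factor = np.nanmax(tm)
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError("no valid off-diagonal tau_max values")
    scaled = mats.tau / factor
    np.fill_diagonal(scaled.values, np.diag(mats.tau.to_numpy()))
    return replace(mats, tau=scaled)


def filter_by_presence(data: OmicsMatrix, fraction: float,
                       groups: pd.Series | None = None) -> OmicsMatrix:
    """Keep features present (non-missing) in >= ``fraction`` of the samples
    of at least one group (all samples as one group when none are given)."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    groups = groups if groups is not None else data.groups
    present = ~data.mask
    if groups is None:
        frac = present.mean(axis=1)[:, None]
    else:
        labels = pd.Series(groups).loc[data.sample_ids]
        frac = np.column_stack([
            present[:, (labels == g).to_numpy()].mean(axis=1)
            for g in labels.unique()])
    keep = (frac >= fraction).any(axis=1)
    if not keep.any():
        raise ValueError(f"presence fraction {fraction} removes every feature")
    return replace(data, values=data.values[keep],
                   feature_ids=[f for f, k in zip(data.feature_ids, keep) if k],
                   provenance=data.provenance + [f"presence_filter:{fraction}"])
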