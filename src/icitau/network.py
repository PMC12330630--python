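"""Feature-feature networks from partial correlations, and how well a set of
annotations partitions them.

Edges come from the tails of the partial-correlation distribution (default
2.5% on each side, 5% total), trimmed to positive weights.  Given a
one-to-many feature -> label annotation map, the partitioning ratio

    Q = sum_i [ within_i / annotated - (outer_i / annotated)^2 ]

compares, per label i, the edge weight concentrated inside the label against
the weight crossing to other labels; more positive Q means the annotations
partition the network better.  With multi-label features Q is not confined
to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnnotatedNetwork", "PartitionScore", "partial_correlation",
           "select_edges", "partition_ratio"]


@dataclass
class AnnotatedNetwork:
    """Symmetric-unique weighted edge list plus a feature -> labels map."""

    edges: pd.DataFrame  # columns: feature_a, feature_b, weight
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        cols = {"feature_a", "feature_b", "weight"}
        if not cols.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(cols)}")
        if (self.edges["feature_a"] == self.edges["feature_b"]).any():
            raise ValueError("self-edges are not allowed")
        self.annotations = {str(f): set(map(str, ls))
                            for f, ls in self.annotations.items()}


@dataclass
class PartitionScore:
    Q: float
    annotated: float
    per_label: pd.DataFrame  # label, within, outer, contribution


def partial_correlation(cor: np.ndarray | pd.DataFrame,
                        ridge_start: float = 1e-8,
                        ridge_max: float = 1.0) -> pd.DataFrame | np.ndarray:
    """Partial correlation via (regularized) inversion of a correlation matrix.

    pcor_ij = -P_ij / sqrt(P_ii P_jj) with P the inverse; the diagonal is set
    to 1.  For ill-conditioned input (p >> n) a ridge lambda*I is added,
    starting at ``ridge_start`` and escalating tenfold until the matrix is
    numerically positive definite.
    """
    is_df = isinstance(cor, pd.DataFrame)
    a = np.asarray(cor, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.isnan(a).any():
        raise ValueError("correlation matrix contains NaN cells; filter "
                         "undefined vectors (e.g. by presence) before "
                         "computing partial correlations")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = 0.0
    while True:
        try:
            np.linalg.cholesky(a + lam * np.eye(a.shape[0]))
            break
        except np.linalg.LinAlgError:
            lam = ridge_start if lam == 0.0 else lam * 10
            if lam > ridge_max:
                raise np.linalg.LinAlgError(
                    "correlation matrix not invertible even with ridge "
                    f"{ridge_max:g}; condition number {np.linalg.cond(a):.3g}")
    prec = np.linalg.inv(a + lam * np.eye(a.shape[0]))
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    if is_df:
        return pd.DataFrame(pcor, index=cor.index, columns=cor.columns)
    return pcor


def select_edges(pcor: pd.DataFrame | np.ndarray,
                 tail_fraction: float = 0.025) -> pd.DataFrame:
    """Tail-quantile edge selection, then positive-weight trimming.

    Thresholds are the ``tail_fraction`` and ``1 - tail_fraction`` empirical
    quantiles (linear interpolation) of the off-diagonal partial-correlation
    distribution; values at or beyond either threshold become candidate
    edges, of which only positive weights survive.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if isinstance(pcor, pd.DataFrame):
        ids = list(pcor.index.astype(str))
        a = pcor.to_numpy(dtype=float)
    else:
        a = np.asarray(pcor, dtype=float)
        ids = [str(i) for i in range(a.shape[0])]
    iu, ju = np.triu_indices(a.shape[0], k=1)
    vals = a[np.tril_indices(a.shape[0], k=-1)]  # full off-diagonal distribution
    vals = np.concatenate([vals, a[iu, ju]])
    lo, hi = np.quantile(vals, [tail_fraction, 1 - tail_fraction])
    w = a[iu, ju]
    keep = ((w <= lo) | (w >= hi)) & (w > 0)
    edges = pd.DataFrame({
        "feature_a": np.array(ids)[iu[keep]],
        "feature_b": np.array(ids)[ju[keep]],
        "weight": w[keep],
    })
    if len(edges) < 2:
        warnings.warn("fewer than two edges survive selection; "
                      "returning an empty network")
    return edges.reset_index(drop=True)


def partition_ratio(net: AnnotatedNetwork) -> PartitionScore:
    """Partitioning ratio Q of an annotated network.

    An edge enters the ledger only when both endpoints carry at least one
    label.  Its weight counts toward ``within_i`` for every label the two
    endpoints share, and toward ``outer_i`` for every label held by exactly
    one endpoint (the other endpoint being annotated to different labels).
    ``annotated`` is the total weight of all both-endpoints-annotated edges.
    """
    ann = net.annotations
    within: dict[str, float] = {}
    outer: dict[str, float] = {}
    annotated = 0.0
    for a, b, w in net.edges[["feature_a", "feature_b", "weight"]].itertuples(index=False):
        la = ann.get(str(a), set())
        lb = ann.get(str(b), set())
        if not la or not lb:
            continue
        annotated += w
        for lab in la & lb:
            within[lab] = within.get(lab, 0.0) + w
        for lab in la ^ lb:
            outer[lab] = outer.get(lab, 0.0) + w
    if annotated == 0.0:
        raise ValueError("no annotated edges")
    labels = sorted(set(within) | set(outer))
    rows = []
    for lab in labels:
        wi = within.get(lab, 0.0)
        oi = outer.get(lab, 0.0)
        contrib = wi / annotated - (oi / annotated) ** 2
        rows.append({"label": lab, "within": wi, "outer": oi,
                     "contribution": contrib})
    per_label = pd.DataFrame(rows)
    return PartitionScore(Q=float(per_label["contribution"].sum()),
                          annotated=annotated, per_label=per_label)
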