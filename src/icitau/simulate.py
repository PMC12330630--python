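"""Synthetic data generators for validating the ICI-Kt methodology.

Every generator emulates an analytical-chemistry intensity scenario:

* :func:`sorted_pair` — two perfectly rank-correlated samples (the same
  log-normal draws sorted ascending, or one reversed), with missingness
  planted among the lowest values of one sample, as happens at the limit of
  detection.
* :func:`noisy_pair` — two statistical replicates of one log-normal base
  draw with additive normal noise, the substrate for the cutoff-censoring
  vs random-missingness comparison.
* :func:`inject_missing` — intensity-cutoff (left-censoring) or
  random-cell missingness, representable as NaN or as zero, with an
  optional naive log-then-zero treatment.
* :func:`dynamic_range_dataset` — 100 samples whose detection floors vary,
  so lower-dynamic-range samples lose their faintest features.
* :func:`planted_block_dataset` — block-correlated features with labels,
  optional low-quality sample; plumbing for the network and outlier tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix

__all__ = ["sorted_pair", "noisy_pair", "inject_missing",
           "dynamic_range_dataset", "half_min_impute",
           "planted_block_dataset", "shuffle_missing"]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sorted_pair(n: int = 1000, meanlog: float = 1.0, sdlog: float = 0.5,
                direction: str = "positive", n_missing: int = 0,
                pool: int = 499, base: np.ndarray | None = None,
                seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Perfectly rank-correlated sample pair with low-end missingness.

    ``n`` log-normal(meanlog, sdlog) draws are sorted ascending into x; y is
    the same values ascending (``direction="positive"``, ICI-Kt exactly 1)
    or descending (``"negative"``, exactly -1).  ``n_missing`` indices are
    then sampled without replacement from the ``pool`` lowest values of y
    and set to NaN — only one member of the pair receives missing values.
    For the negative direction the sampled indices are mirrored (subtracted
    from ``n``) so they still hit the low end of y.

    Pass ``base`` to reuse one draw across a missingness sweep (it is sorted
    here); otherwise a fresh draw is taken from ``seed``.
    """
    if n_missing > pool:
        raise ValueError(f"n_missing must be <= {pool}")
    if n_missing >= n / 2:
        raise ValueError("n_missing must be below half the vector length")
    rng = _rng(seed)
    if base is not None:
        if len(base) != n:
            raise ValueError("base length must equal n")
        base = np.sort(np.asarray(base, dtype=float))
    else:
        base = np.sort(rng.lognormal(mean=meanlog, sigma=sdlog, size=n))
    x = base.copy()
    if direction == "positive":
        y = base.copy()
        idx = rng.choice(pool, size=n_missing, replace=False)
    elif direction == "negative":
        y = base[::-1].copy()
        idx = n - 1 - rng.choice(pool, size=n_missing, replace=False)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    y[idx] = np.nan
    return x, y


def noisy_pair(n: int = 1000, meanlog: float = 1.0, sdlog: float = 0.5,
               noise_sd: float = 0.2, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Two noisy statistical replicates of one log-normal base draw.

    The base intensities are log-normal(meanlog, sdlog); each replicate adds
    independent normal(0, noise_sd) measurement noise to the intensities.
    At these defaults the pair's Kendall-type correlation is about 0.86.
    """
    rng = _rng(seed)
    base = rng.lognormal(mean=meanlog, sigma=sdlog, size=n)
    x = base + rng.normal(0.0, noise_sd, size=n)
    y = base + rng.normal(0.0, noise_sd, size=n)
    return x, y


def inject_missing(x: np.ndarray, y: np.ndarray, scheme: str, level,
                   representation: str = "missing",
                   log_then_zero: bool = False, seed=None):
    """Censor a sample pair by intensity cutoff or at random cells.

    ``scheme="cutoff"`` blanks every value strictly below ``level`` in both
    vectors (left-censoring); ``scheme="random"`` blanks ``level`` cells
    drawn uniformly from the 2 x n cell grid.  ``representation`` picks NaN
    (``"missing"``) or 0 (``"zero"``) for the blanked cells.
    ``log_then_zero`` reproduces the naive pipeline that censors to missing,
    log-transforms what remains, and only then zero-fills the holes.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if scheme == "cutoff":
        if level < 0:
            raise ValueError("cutoff level must be non-negative")
        mx = x < level
        my = y < level
    elif scheme == "random":
        n_cells = x.size + y.size
        if not 0 <= level <= n_cells:
            raise ValueError(f"random level must be in [0, {n_cells}]")
        cells = _rng(seed).choice(n_cells, size=int(level), replace=False)
        mx = np.zeros(x.size, dtype=bool)
        my = np.zeros(y.size, dtype=bool)
        mx[cells[cells < x.size]] = True
        my[cells[cells >= x.size] - x.size] = True
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if log_then_zero:
        x, y = np.log(x), np.log(y)
        fill = 0.0
    elif representation == "zero":
        fill = 0.0
    elif representation == "missing":
        fill = np.nan
    else:
        raise ValueError(f"unknown representation {representation!r}")
    x[mx] = fill
    y[my] = fill
    return x, y


def dynamic_range_dataset(n_features: int = 1000, n_samples: int = 100,
                          meanlog: float = 1.0, sdlog: float = 0.5,
                          noise_sd: float = 0.2, censor_max: float = 1.5,
                          seed=None) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Reference / trimmed matrix pair with per-sample dynamic-range censoring.

    One log-scale base draw of ``n_features`` values spawns ``n_samples``
    noisy samples; values are carried on the log10 scale so differences read
    as orders of magnitude.  Each sample's censor level is its own minimum
    plus a uniform(0, censor_max) draw; trimmed-copy values below that level
    become missing, while the reference copy is untouched.
    """
    rng = _rng(seed)
    base_log = rng.normal(meanlog, sdlog, size=n_features)
    logvals = base_log[:, None] + rng.normal(0.0, noise_sd,
                                             size=(n_features, n_samples))
    vals = np.log10(np.exp(logvals))
    cutoffs = vals.min(axis=0) + rng.uniform(0.0, censor_max, size=n_samples)
    trimmed = vals.copy()
    trimmed[vals < cutoffs[None, :]] = np.nan
    fids = [f"feat_{i}" for i in range(n_features)]
    sids = [f"sample_{j}" for j in range(n_samples)]
    reference = OmicsMatrix(vals, fids, sids,
                            provenance=[f"dynamic_range:censor_max={censor_max}:reference"])
    trimmed_m = OmicsMatrix(trimmed, fids, sids,
                            provenance=[f"dynamic_range:censor_max={censor_max}:trimmed"])
    return reference, trimmed_m


def half_min_impute(data: OmicsMatrix) -> OmicsMatrix:
    """Replace every missing cell with half the smallest observed value in
    the whole dataset — the global imputation baseline for Pearson."""
    vals = data.values.copy()
    if np.isnan(vals).all():
        raise ValueError("no observed values to impute from")
    fill = 0.5 * np.nanmin(vals)
    vals[np.isnan(vals)] = fill
    return replace(data, values=vals,
                   provenance=data.provenance + [f"half_min_impute:{fill:g}"])


def planted_block_dataset(n_features: int = 60, n_samples: int = 24,
                          n_blocks: int = 2, within_cor: float = 0.9,
                          meanlog: float = 1.0, sdlog: float = 0.5,
                          noise_sd: float = 0.2,
                          censor_quantile: float = 0.15,
                          outlier_extra_missing: float = 0.0,
                          n_groups: int = 2, seed=None):
    """Block-correlated feature matrix with labels; optional planted outlier.

    Each feature has a log-normal(meanlog, sdlog) mean intensity shared by
    all samples — this drives realistic sample-sample correlation and puts
    the same faint features at the bottom of every sample.  On top, features
    are split evenly into ``n_blocks`` blocks; a feature's per-sample
    deviation (scale ``noise_sd``) mixes its block's latent factor with
    independent noise so that within-block feature-feature correlation is
    about ``within_cor`` and between-block correlation is about 0.  Values
    are exponentiated to intensities and each sample's lowest
    ``censor_quantile`` fraction is set missing (a detection floor).  If
    ``outlier_extra_missing`` > 0, the last sample additionally loses that
    fraction of its cells at random — a planted low-quality sample.

    Returns (OmicsMatrix with sample groups, feature -> {block label} map,
    outlier sample id or None).
    """
    rng = _rng(seed)
    block = np.arange(n_features) % n_blocks
    mu = rng.normal(meanlog, sdlog, size=n_features)
    factors = rng.normal(0.0, 1.0, size=(n_blocks, n_samples))
    noise = rng.normal(0.0, 1.0, size=(n_features, n_samples))
    z = (np.sqrt(within_cor) * factors[block]
         + np.sqrt(1.0 - within_cor) * noise)
    vals = np.exp(mu[:, None] + noise_sd * z)
    if censor_quantile > 0:
        floors = np.quantile(vals, censor_quantile, axis=0)
        vals[vals < floors[None, :]] = np.nan
    outlier_id = None
    if outlier_extra_missing > 0:
        n_extra = int(round(outlier_extra_missing * n_features))
        idx = rng.choice(n_features, size=n_extra, replace=False)
        vals[idx, -1] = np.nan
        outlier_id = f"sample_{n_samples - 1}"
    fids = [f"feat_{i}" for i in range(n_features)]
    sids = [f"sample_{j}" for j in range(n_samples)]
    groups = pd.Series([f"group_{j % n_groups}" for j in range(n_samples)],
                       index=sids)
    data = OmicsMatrix(vals, fids, sids, groups=groups,
                       provenance=["planted_block_dataset"])
    labels = {fid: {f"block_{b}"} for fid, b in zip(fids, block)}
    return data, labels, outlier_id


def shuffle_missing(data: OmicsMatrix, reference: OmicsMatrix | None = None,
                    seed=None) -> OmicsMatrix:
    """Destroy the left-censoring structure of the missingness.

    Each sample keeps its number of missing cells, but their positions are
    redrawn uniformly over the features.  With ``reference`` (the uncensored
    counterpart matrix) the observed values come from the reference, so only
    the missingness pattern changes; without it the column's values are
    randomly permuted before masking, which also scrambles feature identity
    within the sample.
    """
    rng = _rng(seed)
    n_feat = data.n_features
    src = reference.values if reference is not None else data.values
    if src.shape != data.values.shape:
        raise ValueError("reference shape does not match")
    vals = np.empty_like(data.values)
    for j in range(data.n_samples):
        col = src[:, j].copy()
        if reference is None:
            col = col[rng.permutation(n_feat)]
        n_missing = int(np.isnan(data.values[:, j]).sum())
        col[rng.choice(n_feat, size=n_missing, replace=False)] = np.nan
        vals[:, j] = col
    return replace(data, values=vals,
                   provenance=data.provenance + ["shuffle_missing"])
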