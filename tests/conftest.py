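import numpy as np
import pandas as pd
import pytest

from icitau import OmicsMatrix, ici_kt

NAN = float("nan")


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    # first call compiles the numba kernel; keep that out of timed tests
    ici_kt([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pair_with_missing(rng, n=None, missing_frac=None):
    """Random vector pair with deliberate duplicates and joint/disjoint
    missingness, for oracle-equivalence exercises."""
    n = n if n is not None else int(rng.integers(2, 51))
    # draw from a small integer set to force ties
    x = rng.integers(0, max(2, n // 3), size=n).astype(float)
    y = rng.integers(0, max(2, n // 3), size=n).astype(float)
    frac = missing_frac if missing_frac is not None else rng.uniform(0, 0.4)
    n_miss = int(frac * n)
    if n_miss:
        x[rng.choice(n, size=n_miss, replace=False)] = np.nan
        joint = rng.random() < 0.5
        if joint and n_miss < n:
            # overlap some of y's missing cells with x's
            y[rng.choice(np.flatnonzero(np.isnan(x)),
                         size=max(1, n_miss // 2), replace=False)] = np.nan
        y[rng.choice(n, size=n_miss, replace=False)] = np.nan
    return x, y


@pytest.fixture
def four_feature_matrix():
    """The worked 4-feature example: samples a=(NA,2,3,4), b=(5,NA,7,8)."""
    vals = np.array([[NAN, 5.0], [2.0, NAN], [3.0, 7.0], [4.0, 8.0]])
    return OmicsMatrix(vals, [f"f{i}" for i in range(4)], ["a", "b"])


@pytest.fixture
def grouped_matrix(rng):
    """Small two-group matrix with left-censored missingness."""
    n_feat, n_samp = 60, 10
    base = rng.lognormal(1, 0.5, n_feat)
    vals = base[:, None] + rng.normal(0, 0.2, (n_feat, n_samp))
    cuts = np.quantile(vals, 0.2, axis=0)
    vals[vals < cuts[None, :]] = np.nan
    sids = [f"s{j}" for j in range(n_samp)]
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=sids)
    return OmicsMatrix(vals, [f"f{i}" for i in range(n_feat)], sids,
                       groups=groups)
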