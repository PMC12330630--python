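# icitau

Information-content-informed Kendall-tau (ICI-Kt) correlation for omics
matrices whose missing values are mostly **left-censored** — analytes that
fell below the limit of detection rather than dropped out at random.

Standard practice either discards missing entries (pairwise-complete
correlation) or imputes them before correlating. Both treat "not detected"
as "no information". In intensity data from mass spectrometry, RNA-seq and
similar platforms, a missing value usually *is* information: the analyte was
below everything that was observed. `icitau` builds that reading directly
into the Kendall framework and ships the companion diagnostics needed to use
it responsibly.

## The statistic

For two vectors x, y with missing entries, a pair of indices *(i, j)* is
classified by treating "missing" as smaller than every observed value: a
pair is concordant when the x- and y-orderings agree under that reading,
discordant when they disagree, and tied in a vector when both entries are
equal or both missing. The coefficient is the usual tau-b,

    tau = (n_con − n_dis) / sqrt((n_tot − n_xtie)(n_tot − n_ytie)),

with the missingness ties folded into *n_xtie*, *n_ytie*. Operationally this
equals classic tau-b after replacing missing entries with any sentinel below
the observed minimum, which is what the O(n log n) mergesort path does.
Three companions complete the methodology:

- **tau_max** = (n_tot − n_xtie − n_ytie + n_tie) / sqrt((n_tot − n_xtie)(n_tot − n_ytie)),
  the largest tau-b the pair's tie structure allows; the dataset-wide
  maximum can rescale a whole correlation matrix.
- **completeness**, the fraction of features missing in neither vector;
  multiplied elementwise with ICI-Kt it gives the quality-sensitive IKC
  metric.
- a **binomial left-censorship test**: under a detection limit, observed
  values of partially-missing features fall below their sample medians with
  probability near 1; under random dropout, near 0.5. Run it before trusting
  the left-censoring interpretation.

Two perspectives are available: *global* keeps co-missing entries as ties in
both vectors (every pair over the same feature set sees the same number of
comparisons), *local* drops them first (natural for a two-sample
comparison).

On top of the pair statistic the package provides all-pairs correlation
matrices under seven method codes (IK, IKC, Kt, PB, PN0, PL1, PL — ICI-Kt
and the conventional alternatives it is compared against), median-correlation
outlier detection with Tukey-fence flagging, partial-correlation
feature-feature networks scored by an annotation partitioning ratio Q, and
generators for all the simulation studies.

## Worked example

```python
import numpy as np
from icitau import ici_kt

nan = np.nan
x = np.array([nan, 2.0, 3.0, 4.0])   # sample 1: feature 0 not detected
y = np.array([5.0, nan, 7.0, 8.0])   # sample 2: feature 1 not detected
res = ici_kt(x, y, perspective="global")
print(res.tau, res.tau_max, res.completeness)
```

prints

```
0.6666666666666666 1.0 0.5
```

The disjoint missingness creates one discordant pair out of six (x says
feature 0 < feature 1, y says the opposite), so tau = (5 − 1)/6 ≈ 0.667 —
whereas a pairwise-complete analysis would only see the two features shared
by both samples and report 1.0. Completeness 0.5 records that half the
feature space was missing somewhere.

The `examples/` directory holds one short script per capability
(`01_pairwise_correlation.py` … `06_simulation_studies.py`); each builds a
small synthetic input, runs the method and prints what the numbers mean.
For instance `python examples/06_simulation_studies.py` prints (seeded):

```
sorted-pair sweep (0-499 low values missing):
  no-missing ICI-Kt: +1.000 / -1.000
  max |ICI-Kt - (+/-1)|        : 0.1908
  max Pearson(complete) change : 0.00255
```

— low-end missingness moves ICI-Kt by up to ~0.19 while pairwise-complete
Pearson barely notices, which is exactly the sensitivity the statistic is
designed to have.

A thin CLI wraps the same functions for shell use:

```sh
icitau correlate --input matrix.tsv --method IK --method IKC --output-dir out/
icitau censor-test --input matrix.tsv --metadata meta.tsv
icitau outliers --input matrix.tsv --metadata meta.tsv --method IKC
icitau network --input matrix.tsv --annotations ann.tsv
icitau simulate sorted-pair --seed 7 --out pair.tsv
```

## Layout

- `src/icitau/core.py` — pair statistic: brute-force census, mergesort fast
  path, tau_max, completeness
- `src/icitau/matrix.py` — `OmicsMatrix`, method encodings, all-pairs
  matrices, tau_max scaling, presence filtering
- `src/icitau/censorship.py` — rank profiles and the binomial test
- `src/icitau/outliers.py` — median correlations, scores, Tukey fences,
  group spread
- `src/icitau/network.py` — partial correlation, tail-edge selection, Q
- `src/icitau/simulate.py` — synthetic-data generators
- `src/icitau/experiments.py` — the canned simulation studies
- `src/icitau/io.py`, `src/icitau/cli.py` — file formats and the CLI

See `docs/methods.md` for the modelling assumptions, parameter choices and
limitations.
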