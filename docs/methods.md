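# Methods

## The model of missingness

`icitau` assumes that a missing cell in an intensity matrix is, with high
probability, a *left-censored* observation: the true value existed but fell
below the effective detection limit of the instrument/preparation for that
sample. Under that assumption "missing" carries rank information — it is
below every observed value in its vector — and the Kendall pair census can
use it. The package deliberately does **not** assume the limit is the same
in every sample; per-sample detection floors are exactly the regime (the
dynamic-range study) where global imputation schemes break down and the
rank-based treatment stays stable.

The assumption is checkable, and should be checked: the binomial
left-censorship test gives an estimate near 1 when the assumption holds and
near 0.5 under missing-at-random dropout, and the median-rank profile shows
the monotone decrease of median rank with missingness count that a detection
limit produces. Randomly missing values are *not* treated specially — they
enter the census the same way and actively pull the correlation down, which
is the desired behaviour for quality control but means ICI-Kt on
genuinely-missing-at-random data is biased relative to pairwise-complete
tau-b.

## Pair census and coefficient

A pair *(i, j)* contributes, with missing ordered below all observed values:
concordant if the x- and y-orderings agree, discordant if they disagree,
tied in x (and/or y) if the two entries are equal observed values or both
missing. `n_commontie` counts pairs tied in both vectors at once — common
missingness plus coincidentally equal observed pairs — so that
`n_con + n_dis + (n_xtie + n_ytie − n_commontie) = n_tot` is an identity
and `tau <= tau_max` holds by construction.

The production path replaces missing entries with
`min(observed values of the pair) − 1.0` and runs a stable bottom-up
mergesort count of y-inversions after a lexicographic (x, y) sort —
O(n log n), numba-compiled. Any strictly smaller sentinel yields identical
ranks (property-tested); −1.0 just avoids floating-point adjacency.
The brute-force rule enumeration is kept as a first-class function and the
two are asserted equal to 1e−12 on ≥1000 randomized pairs per test run.
`scipy.stats.kendalltau` serves as an additional independent cross-check on
sentinel-imputed vectors; it is never the implementation.

Degenerate inputs: fewer than two effective observations or an all-missing
vector raise `DegenerateInputError`; an entirely-tied vector (zero tau-b
denominator) raises `UndefinedCorrelationError` carrying the census, and at
the matrix level such cells become NaN with a warning rather than aborting
the run.

The optional p-value is the two-sided normal approximation with the
standard tie-corrected tau-b variance. It is exposed because users expect
one from a correlation routine; none of the package's own procedures
consume it.

## Perspectives, tau_max, completeness

*Global* keeps co-missing index pairs as ties in both vectors; every pair of
samples over the same feature set then sees the same `n_tot`, which makes
values comparable across a matrix and gives tau_max its meaning. *Local*
drops co-missing indices first and suits an isolated two-sample comparison.
Dataset-wide rescaling divides every tau by the maximum off-diagonal
tau_max — one factor for the whole matrix, so the best-endowed pair can
reach 1 while sign and ordering are preserved; the self-correlation diagonal
is left at 1. The direction (division, dataset-wide) is a design choice:
a single "equally applied" factor that maps the theoretical ceiling to 1.
Completeness uses the full feature count of the dataset, not the
pair-trimmed length, and IKC multiplies completeness into ICI-Kt *without*
tau_max scaling; the two adjustments are independent and composable.

## Method codes

All seven codes first normalise the missing/zero encoding from the shared
convention that zero and missing are interchangeable "not detected"
markers: IK/IKC/Kt/PN0 convert zeros to missing; PB converts missing to
zero; PL1 zero-fills then applies log(x+1); PL applies log(x) and masks
non-finite results. Pearson variants use pairwise-complete observations
(pandas `corr`). Kt is pairwise-complete classic tau-b. On data without
zeros PB = PN0, and on data without missingness IK reduces exactly to
classic tau-b — both are regression-tested.

Parallelism: the pair list is statically partitioned across joblib workers
and reassembled by pair index; results are bit-identical for any worker
count.

## Censorship diagnostics

Ranks are ascending (rank 1 = lowest intensity in the sample) with average
ranks at ties, computed per sample over present features only. The binomial
test counts a present value of a partially-missing feature as a success when
it is **strictly** below its sample median (ties count as failures), pools
successes and trials across treatment groups, and tests one-sided against
0.5 (`scipy.stats.binomtest`). The confidence bound is the one-sided 95%
exact Clopper–Pearson lower limit, reported as "lower – 1.00"; the
one-sided choice follows from the direction of the hypothesis (only an
excess of below-median values is evidence of left-censoring).

## Outlier detection

Per sample: the median of its correlations to the other samples of its own
group (self excluded; singleton groups are an error), transformed to
`log(1 − cor_median)`. Fences are Tukey hinges (R `fivenum` depths, not
interpolated quantiles, matching boxplot statistics); a sample is flagged
only when its score exceeds `upper hinge + 1.5 × (upper − lower hinge)`.
Only the high end (poorly correlating samples) can be flagged. A median
correlation of exactly 1 yields a score of −∞; such samples are kept in the
report, excluded from hinge computation, and can never be flagged. Fences
pool scores across groups by default (medians are already within-group),
mirroring a single flagging rule for the whole run. The presence-fraction
sweep refilters features (present in ≥ fraction of at least one group's
samples), recomputes the matrix and re-flags; MAD summaries use the 1.4826
normal-consistency constant.

## Networks and partitioning

Partial correlations come from the inverse correlation matrix,
`pcor_ij = −P_ij / sqrt(P_ii P_jj)`; because feature matrices routinely have
p ≫ n, a ridge λI is added when the matrix is not numerically positive
definite, starting at 1e−8 and escalating tenfold to at most 1.0 before
erroring with the condition number. Edges are the off-diagonal values at or
beyond the 2.5% / 97.5% empirical quantiles (linear interpolation; threshold
ties included), then trimmed to positive weights. Features should be
presence-filtered (≥25% of some class) before feature-feature correlation.

The partitioning ratio is
`Q = Σ_i [ within_i/annotated − (outer_i/annotated)² ]` over labels *i*.
An edge enters the ledger only when **both** endpoints carry at least one
label; its weight counts toward `within_i` for every shared label and
toward `outer_i` for every label held by exactly one endpoint.
Single-annotated-endpoint edges are excluded from all three sums — the
defensible alternative (counting them in `annotated`) only shrinks every
term uniformly and does not change orderings in our fixtures. With
multi-label features Q is not confined to [0, 1]; comparisons should be
within one dataset across methods.

## Synthetic data: what it emulates, what it does not

- `sorted_pair`: one log-normal(meanlog 1, sdlog 0.5) draw of 1000 values
  sorted into a perfectly rank-correlated pair (second member reversed for
  the negative orientation); up to 499 missing cells planted among the 499
  lowest values of one member (mirrored indices for the reversed member).
  A sweep reuses one fixed base draw so that measured correlation changes
  isolate the censoring effect rather than draw-to-draw variation.
- `noisy_pair`: normal(0, 0.2) measurement noise added on the intensity
  scale to a shared log-normal base draw; the resulting pair has ICI-Kt
  ≈ 0.86 before any censoring, and the cutoff grid 0→1.5 censors a
  realistic low tail.
- `inject_missing`: intensity-cutoff censoring or uniformly random cell
  blanking, encoded as NaN or zero; `log_then_zero` reproduces the naive
  log-transform-then-zero-fill pipeline.
- `dynamic_range_dataset`: 1000 features × 100 samples on the log10 scale;
  each sample's censor level is its own minimum plus uniform(0, censor_max)
  with censor_max ∈ {0.5, 1, 1.5} for low/medium/high dynamic-range
  variability. Half-minimum imputation (half the smallest observed value in
  the trimmed dataset) is the Pearson baseline.
- `planted_block_dataset`: per-feature log-normal mean profile (gives
  sample-sample correlation ≈ 0.86 at the defaults and puts the same faint
  features at the bottom of every sample) plus block latent factors mixing
  to a chosen within-block feature correlation; per-sample quantile
  censoring; optionally one sample with extra random missingness as a
  planted outlier. For the network-partitioning property the tests use
  sdlog 0.1 / noise_sd 0.5 / censor_quantile 0.3 so that *which* features
  are censored in a sample is driven by the block factors — the regime in
  which missingness actually carries block information; with mean-dominated
  censoring the same features are missing everywhere and the comparison
  degenerates.

None of the generators emulate count distributions (negative binomial
RNA-seq), library-size normalisation, or batch structure. Passing tests
show the statistic behaves as designed under left-censoring and random
missingness; they do not certify performance on any particular real
platform — run the censorship test on real data first.

### A note on the Pearson companion in the sorted-pair study

The sorted pair is perfectly linear on the **log** scale (Pearson +1 /
−0.997) but markedly non-linear on the intensity scale for the reversed
member (Pearson ≈ −0.8, and tail removal then moves it by ~0.1). The study
therefore evaluates pairwise-complete Pearson on log intensities, where its
changes (≤ ~0.003) genuinely measure the effect of the dropped points;
ICI-Kt is rank-based and identical on either scale.

## Numerical and testing choices

- Tolerances: fast path vs brute force at 1e−12 (pure integer census, so
  the only float work is the final division); statistical assertions at the
  scale of their Monte-Carlo noise (e.g. start tau 0.86 ± 0.03 over
  replicate averages).
- Problem sizes in the test-suite studies: 1000-value pairs for the sweeps
  (full 0–499 grid), 1000 × 100 for the dynamic-range study, 100-replicate
  random-missingness averages, 80 × 40 planted-block matrices — the sizes
  the simulation design itself specifies, kept because the statistics are
  already stable there.
- Complexity is validated by regression (RSS of time against a + b·n log n
  vs a + b·n²) rather than wall-clock thresholds.
- Determinism: every generator takes a seed or Generator; hypothesis
  property tests run derandomized.

## Known limitations

- ICI-Kt interprets *all* missingness as below-detection; heavy
  missing-at-random contamination biases it downward (by design for QC,
  but not an estimate of the latent correlation).
- The normal-approximation p-value is inaccurate for n ≲ 10 or extreme tie
  loads; no exact permutation option is provided.
- The ridge-regularized inverse is a pragmatic partial-correlation
  estimator for p ≫ n, not a tuned shrinkage estimator; Q comparisons
  across methods on the same data are meaningful, absolute Q values less so.
- `local` tau_max is computed from the same census but its dataset-wide
  comparability argument only holds under the global perspective.
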