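"""Pairwise ICI-Kt on two short vectors with missing values.

Two 4-feature samples each miss one (different) feature.  Treating missing
as "below everything observed" turns the missing-vs-observed comparisons
into concordant/discordant evidence instead of discarding them.
"""

import numpy as np

from icitau import ici_kt

nan = np.nan
x = np.array([nan, 2.0, 3.0, 4.0])   # sample 1: feature 0 not detected
y = np.array([5.0, nan, 7.0, 8.0])   # sample 2: feature 1 not detected

res = ici_kt(x, y, perspective="global", p_value=True)
print(f"tau          = {res.tau:.5f}")
print(f"tau_max      = {res.tau_max:.5f}")
print(f"completeness = {res.completeness:.2f}")
print(f"p_value      = {res.p_value:.3f}")
print(f"pair census  = {res.counts}")

# The disjoint missingness creates one discordant pair (feature 0 vs 1:
# x says 0 < 1, y says 0 > 1), so tau = (5-1)/6 ~ 0.667 rather than the
# 1.0 a pairwise-complete analysis of the two remaining shared features
# would report; completeness 0.5 records that half the features were
# missing in at least one sample.

# With co-missing features the two perspectives differ:
x2 = np.array([nan, nan, 3.0, 4.0])
y2 = np.array([nan, 6.0, 7.0, 8.0])
print(f"\nglobal (co-missing kept as ties): {ici_kt(x2, y2).tau:.5f}")
print(f"local  (co-missing dropped):      {ici_kt(x2, y2, 'local').tau:.5f}")
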