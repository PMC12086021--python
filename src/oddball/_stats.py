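"""Small statistical helpers shared across modules.

All population comparisons in this package are nonparametric and two-sided:
the Wilcoxon signed-rank test for paired samples (each neuron contributes a
matched pair of values under the two conditions) and the Mann-Whitney U test
for independent groups.  This module wraps :mod:`scipy.stats` with the
degenerate-case conventions used throughout:

* fewer than ``min_n`` valid pairs -> the p-value is undefined (NaN);
* all paired differences exactly zero -> the test statistic is undefined and
  the comparison is treated as maximally null (p = 1).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

#: Validity floor for the signed-rank test; below this the exact null
#: distribution cannot reach p < 0.05 two-sided.
MIN_PAIRS = 6


def paired_wilcoxon(x, y, min_n: int = MIN_PAIRS) -> tuple[float, int]:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    NaN pairs are dropped; zero differences are dropped (standard Wilcoxon
    handling; exact distribution for small n without ties, normal
    approximation with continuity correction otherwise).  Returns ``(p, n)``
    where ``n`` is the number of valid pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < min_n:
        return math.nan, n
    d = x - y
    if np.all(d == 0):
        return 1.0, n
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method="auto")
    return float(res.pvalue), n


def mannwhitney_u(x, y, min_n: int = MIN_PAIRS) -> tuple[float, int, int]:
    """Two-sided Mann-Whitney U p-value for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if min(x.size, y.size) < min_n:
        return math.nan, int(x.size), int(y.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue), int(x.size), int(y.size)


def nanmedian(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.all(np.isnan(values)):
        return math.nan
    return float(np.nanmedian(values))
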