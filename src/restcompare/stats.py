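"""One-way ANOVA from the standard sums-of-squares decomposition.

F = (between-group SS / (k-1)) / (within-group SS / (n-k)); the p-value is
the upper tail of the F(k-1, n-k) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across ``groups``.

    Requires at least two groups of at least two values each.  Degenerate
    cases are handled explicitly: all values identical gives F = 0, p = 1;
    zero within-group variance with unequal means gives F = inf, p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0)
        return AnovaResult(float("inf"), dfb, dfw, 0.0)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sstats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p)
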