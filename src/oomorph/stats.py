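"""Group-level statistics for pediatric-vs-adult comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "mann_whitney"]

#: product n1*n2 up to which the exact null distribution is used (no ties)
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class GroupComparison:
    """A two-group Mann–Whitney comparison of one variable."""

    variable: str
    u_statistic: float
    p_value: float  # two-tailed
    n_a: int
    n_b: int
    median_a: float
    median_b: float

    @property
    def significant(self) -> bool:
        """Two-tailed significance at the conventional 0.05 level."""
        return self.p_value < 0.05


def mann_whitney(group_a, group_b, variable: str = "value") -> GroupComparison:
    """Two-tailed Mann–Whitney U test between two samples.

    Uses the exact null distribution for small samples (n1·n2 ≤ 400, no
    ties) and the tie-corrected normal approximation with continuity
    correction otherwise.  Empty groups are an error.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if a.size * b.size <= _EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
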