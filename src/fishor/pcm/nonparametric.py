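"""Plain (non-phylogenetic) group comparison."""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def group_compare(group0, group1) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two groups of values.

    Exact p-value when the combined sample size is at most 20 and there
    are no ties; normal approximation with tie correction otherwise.
    Returns (U statistic of group0, p-value).
    """
    x = np.asarray(list(group0), dtype=float)
    y = np.asarray(list(group1), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    small = len(combined) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
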