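"""Significance tests used across the analyses.

Two-group comparisons use Welch's two-tailed t-test; multi-group
comparisons use one-way ANOVA followed by a Tukey honestly-significant-
difference (HSD) test on the group means, matching standard practice for
cytoneme-count and intensity comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["welch_t", "anova_tukey"]


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-tailed p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def anova_tukey(groups: dict | list, alpha: float = 0.05):
    """One-way ANOVA plus Tukey HSD pairwise table.

    Parameters
    ----------
    groups
        Mapping of group name to sample, or a list of samples (named by
        position).

    Returns
    -------
    (F, p, table)
        ANOVA F statistic and p value, and a DataFrame of pairwise HSD
        comparisons (group1, group2, meandiff, p_adj, lower, upper, reject).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
        raise ValueError("zero within-group variance everywhere")

    F, p = sps.f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return float(F), float(p), table
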