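"""Statistical decision tree for group comparisons.

Data are gated for normality (Shapiro-Wilk for n < 50, Lilliefors-corrected
Kolmogorov-Smirnov otherwise); normally distributed groups are compared with
Welch's t-test (or a paired t-test), non-normal groups with the Mann-Whitney
test — exact when min(n) <= 8, tie-corrected normal approximation otherwise.
Many-to-one families use one-way ANOVA followed by Dunnett's multiple
comparison. Results carry the printed significance labels: 'ns' (p > 0.05),
'*' (p < 0.05), '**' (p < 0.01), '***' (p < 0.001). Summaries are reported as
mean +/- SEM. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparisonResult",
    "MeanSem",
    "significance_label",
    "normality_gate",
    "compare_groups",
    "mann_whitney",
    "dunnett",
    "mean_sem",
]

EXACT_MW_MAX_N = 8


@dataclass
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    normality_p_values: tuple[float, ...] = ()
    significance_label: str = "ns"
    notes: str = ""


@dataclass
class MeanSem:
    mean: float
    sem: float
    n: int
    sem_estimable: bool = True


def significance_label(p: float) -> str:
    """Map a p-value to the printed star convention."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mean_sem(x) -> MeanSem:
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    if x.size == 1:
        return MeanSem(mean=float(x[0]), sem=0.0, n=1, sem_estimable=False)
    return MeanSem(
        mean=float(np.mean(x)),
        sem=float(np.std(x, ddof=1) / np.sqrt(x.size)),
        n=int(x.size),
    )


def normality_gate(samples) -> tuple[str, tuple[float, ...]]:
    """Test each group for normality; 'normal' only if every group's p > 0.05.

    Shapiro-Wilk for n < 50, Lilliefors-corrected KS otherwise. Constant
    samples are treated as non-normal (p reported as 0).
    """
    p_values = []
    for x in samples:
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValueError("normality testing needs n >= 3 per group")
        if np.ptp(x) == 0:
            p_values.append(0.0)
            continue
        if x.size < 50:
            p_values.append(float(sps.shapiro(x).pvalue))
        else:
            p_values.append(float(lilliefors(x, dist="norm")[1]))
    verdict = "normal" if all(p > 0.05 for p in p_values) else "non_normal"
    return verdict, tuple(p_values)


def _midrank_u(pooled_ranks, idx_x, n_x, n_y):
    """Mann-Whitney U of group x from pooled mid-ranks."""
    rank_sum = pooled_ranks[idx_x].sum()
    return rank_sum - n_x * (n_x + 1) / 2.0


def _exact_mw_with_ties(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration with mid-rank ties.

    Enumerates all C(n_x+n_y, n_x) group assignments of the pooled sample and
    counts those whose U deviates from its null mean at least as much as the
    observed U.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = nx * ny / 2.0
    u_obs = _midrank_u(ranks, np.arange(nx), nx, ny)
    dev_obs = abs(u_obs - mu)
    total = comb(nx + ny, nx)
    hits = 0
    for idx in combinations(range(nx + ny), nx):
        u = _midrank_u(ranks, np.array(idx), nx, ny)
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney(x, y) -> GroupComparisonResult:
    """Two-sided Mann-Whitney test.

    Exact for min(n) <= 8 (scipy's exact distribution when the pooled sample
    is tie-free, full enumeration with mid-rank ties otherwise); tie-corrected
    normal approximation for larger samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(x.size, y.size) <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size == pooled.size:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            stat, p = float(res.statistic), float(res.pvalue)
            notes = "exact (tie-free)"
        else:
            stat, p = _exact_mw_with_ties(x, y)
            notes = "exact (mid-rank enumeration)"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        notes = "tie-corrected normal approximation"
    return GroupComparisonResult(
        test_name="mann_whitney",
        statistic=stat,
        p_value=p,
        n_per_group=(x.size, y.size),
        significance_label=significance_label(p),
        notes=notes,
    )


def compare_groups(x, y, paired: bool = False, forced_test: str | None = None) -> GroupComparisonResult:
    """Two-group comparison routed through the normality gate.

    Normal data use Welch's t-test (paired data a paired t-test); non-normal
    data use Mann-Whitney. ``forced_test`` in {'welch_t', 'paired_t',
    'mann_whitney'} bypasses the gate. Paired comparisons require equal
    lengths.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal-length samples")

    normality_p: tuple[float, ...] = ()
    if forced_test is None:
        verdict, normality_p = normality_gate([x, y])
        if verdict == "normal":
            forced_test = "paired_t" if paired else "welch_t"
        else:
            forced_test = "mann_whitney"

    if forced_test == "welch_t":
        res = sps.ttest_ind(x, y, equal_var=False)
        out = GroupComparisonResult(
            test_name="welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_per_group=(x.size, y.size),
        )
    elif forced_test == "paired_t":
        if x.size != y.size:
            raise ValueError("paired comparison requires equal-length samples")
        res = sps.ttest_rel(x, y)
        p, notes = float(res.pvalue), ""
        if np.isnan(p):  # zero-variance differences
            p, notes = 1.0, "degenerate: zero-variance paired differences"
        out = GroupComparisonResult(
            test_name="paired_t",
            statistic=float(res.statistic),
            p_value=p,
            n_per_group=(x.size, y.size),
            notes=notes,
        )
    elif forced_test == "mann_whitney":
        out = mann_whitney(x, y)
    else:
        raise ValueError(f"unknown test {forced_test!r}")
    out.normality_p_values = normality_p
    out.significance_label = significance_label(out.p_value)
    return out


def dunnett(groups, control_index: int = 0) -> pd.DataFrame:
    """Many-to-one Dunnett comparison against a control group.

    Returns one row per treatment group with the t statistic against the
    control (pooled error across all groups), the familywise-adjusted p-value,
    and the unadjusted two-sided t p-value (df = N - k) for reference.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need a control plus at least one treatment group")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    control = arrays[control_index]
    treatments = [g for i, g in enumerate(arrays) if i != control_index]
    labels = [i for i in range(len(arrays)) if i != control_index]

    res = sps.dunnett(*treatments, control=control)
    n_total = sum(g.size for g in arrays)
    df = n_total - len(arrays)
    rows = []
    for lab, stat, p_adj in zip(labels, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
        p_unadj = 2.0 * sps.t.sf(abs(stat), df)
        rows.append(
            {
                "group_index": lab,
                "statistic": float(stat),
                "p_adjusted": float(p_adj),
                "p_unadjusted": float(p_unadj),
                "significance": significance_label(float(p_adj)),
            }
        )
    return pd.DataFrame(rows)
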