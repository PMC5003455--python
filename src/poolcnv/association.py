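"""Case-control association tests on pooled CNV data.

With only 8 case and 8 control pools, asymptotic rank tests are unreliable,
so the Wilcoxon rank-sum p-value is computed *exactly* by enumerating all
C(16, 8) = 12 870 assignments of the observed values to the two groups,
using mid-ranks for ties (the exact conditional null distribution given the
tie pattern).  The smallest attainable two-sided p is therefore
2/12 870 ≈ 1.55e-4.

Three analyses are provided:

- :func:`burden_analysis` — per-pool CNV counts, stratified by status
  (gain/loss/both) and minimum length (≥100 kb, ≥500 kb), compared between
  groups with the exact rank-sum test;
- :func:`region_signal_test` — per-pool median LRR over the markers inside
  a region, compared with both a two-sided Welch t-test and the exact
  rank-sum test;
- :func:`power_two_sample_t` — analytic power of the two-sided two-sample
  t-test via the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import CNVRegion, region_length_kb
from .simulate import PooledDataset
from .caller import CNVCall

__all__ = [
    "BurdenStratum",
    "SignalTestResult",
    "exact_rank_sum_test",
    "burden_analysis",
    "region_signal_test",
    "power_two_sample_t",
    "DEFAULT_STRATA",
]

DEFAULT_STRATA: tuple[tuple[float, str], ...] = (
    (100.0, "both"),
    (100.0, "gain"),
    (100.0, "loss"),
    (500.0, "both"),
    (500.0, "gain"),
    (500.0, "loss"),
)


def exact_rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Enumerates every assignment of the pooled observations into groups of
    size len(x) and len(y); ties get mid-ranks.  The two-sided p is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))`` where W is the rank sum of
    the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if math.comb(x.size + y.size, x.size) > 1_000_000:
        raise ValueError("group sizes too large for exact enumeration")
    ranks = stats.rankdata(np.concatenate([x, y]))
    n, m = x.size, y.size
    w_obs = ranks[:n].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n + m), n)])
    eps = 1e-9  # guard float rank sums
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass(frozen=True)
class BurdenStratum:
    """Burden comparison for one (size, status) stratum."""

    size_min_kb: float
    cnv_type: str  # both | gain | loss
    n_unique_case: int
    n_unique_control: int
    mean_per_case_pool: float
    mean_per_control_pool: float
    p_wilcoxon: float  # NaN when undefined (no calls anywhere)


def _stratum_calls(calls: Sequence[CNVCall], size_min_kb: float, cnv_type: str) -> list[CNVCall]:
    return [
        c
        for c in calls
        if (cnv_type == "both" or c.status == cnv_type)
        and region_length_kb(c.start, c.end) >= size_min_kb
    ]


def burden_analysis(
    calls_by_pool: Mapping[str, Sequence[CNVCall]],
    manifest: pd.DataFrame,
    strata: Sequence[tuple[float, str]] = DEFAULT_STRATA,
) -> list[BurdenStratum]:
    """Compare per-pool CNV counts between groups, stratum by stratum.

    "Unique" counts are the number of distinct regions after a within-group
    union of the stratum's calls.  The Wilcoxon p is reported as NaN when no
    pool has any call in the stratum.
    """
    from .regions import union_regions  # deferred: regions imports CNVCall too

    case_pools = list(manifest.loc[manifest["group"] == "case", "pool_id"])
    control_pools = list(manifest.loc[manifest["group"] == "control", "pool_id"])
    if len(case_pools) != 8 or len(control_pools) != 8:
        import warnings

        warnings.warn(
            f"burden analysis designed for 8v8 pools, got "
            f"{len(case_pools)}v{len(control_pools)}",
            stacklevel=2,
        )
    out = []
    for size_min, cnv_type in strata:
        filtered = {
            pool: _stratum_calls(calls_by_pool.get(pool, ()), size_min, cnv_type)
            for pool in (*case_pools, *control_pools)
        }
        case_counts = [len(filtered[p]) for p in case_pools]
        control_counts = [len(filtered[p]) for p in control_pools]
        if sum(case_counts) + sum(control_counts) == 0:
            p = math.nan
        else:
            p = exact_rank_sum_test(case_counts, control_counts)
        n_uc = len(
            union_regions(
                {p_: filtered[p_] for p_ in case_pools},
                manifest.loc[manifest["group"] == "case"],
            )
        )
        n_uk = len(
            union_regions(
                {p_: filtered[p_] for p_ in control_pools},
                manifest.loc[manifest["group"] == "control"],
            )
        )
        out.append(
            BurdenStratum(
                size_min_kb=size_min,
                cnv_type=cnv_type,
                n_unique_case=n_uc,
                n_unique_control=n_uk,
                mean_per_case_pool=float(np.mean(case_counts)),
                mean_per_control_pool=float(np.mean(control_counts)),
                p_wilcoxon=p,
            )
        )
    return out


@dataclass(frozen=True)
class SignalTestResult:
    region: CNVRegion
    case_medians: tuple[float, ...]
    control_medians: tuple[float, ...]
    p_t: float  # Welch t, two-sided; NaN when both groups are constant
    p_wilcoxon: float


def region_signal_test(
    region: CNVRegion, dataset: PooledDataset, markers: pd.DataFrame | None = None
) -> SignalTestResult:
    """Test case-vs-control pooled signal inside one region.

    For every pool the median LRR over the (QC-retained) markers falling in
    ``[start, end]`` on the region's chromosome is taken; the 8-vs-8 medians
    are compared with a two-sided Welch t-test and the exact rank-sum test.
    Pass the QC-retained marker table as ``markers`` (defaults to the full
    signal table).  Raises ``ValueError`` if no marker falls in the region.
    """
    if markers is None:
        markers = dataset.signals
    sub = markers.loc[
        (markers["chrom"] == region.chrom)
        & (markers["position"] >= region.start)
        & (markers["position"] <= region.end)
    ]
    if sub.empty:
        raise ValueError(
            f"no markers in region {region.chrom}:{region.start}-{region.end}"
        )
    case_pools = dataset.pools_in_group("case")
    control_pools = dataset.pools_in_group("control")
    case_med = [float(sub[f"{p}.lrr"].median()) for p in case_pools]
    control_med = [float(sub[f"{p}.lrr"].median()) for p in control_pools]

    if np.var(case_med) == 0.0 and np.var(control_med) == 0.0:
        p_t = math.nan  # zero variance in both groups: t undefined
    else:
        p_t = float(stats.ttest_ind(case_med, control_med, equal_var=False).pvalue)
    p_w = exact_rank_sum_test(case_med, control_med)
    return SignalTestResult(
        region=region,
        case_medians=tuple(case_med),
        control_medians=tuple(control_med),
        p_t=p_t,
        p_wilcoxon=p_w,
    )


def power_two_sample_t(
    delta: float, sd: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-sample t-test (equal n, common SD).

    Uses the noncentral t distribution with noncentrality
    ``delta / (sd * sqrt(2/n))`` and ``2n − 2`` degrees of freedom.  At
    ``delta = 0`` the power equals ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    ncp = delta / (sd * math.sqrt(2.0 / n_per_group))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - stats.nct.cdf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    return float(power)
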