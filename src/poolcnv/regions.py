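"""Region-level filtering, gap merging, and the cross-pool region union.

All coordinates are 1-based inclusive, so an interval's length in bp is
``end − start + 1`` and two intervals overlap iff
``max(starts) <= min(ends)``.  The pipeline order is: minimum-marker filter
→ gain-quality filters → per-pool gap merge → cross-pool union.  Merged
calls are not re-subjected to the earlier filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import CNVCall
from .config import RegionFilterParams

__all__ = [
    "CNVRegion",
    "region_length_kb",
    "overlap",
    "filter_min_markers",
    "filter_gain_quality",
    "merge_gaps",
    "union_regions",
    "count_unique_regions",
]


def region_length_kb(start: int, end: int) -> float:
    """Inclusive interval length in kb: (end − start + 1) / 1000, unrounded."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return (end - start + 1) / 1000.0


def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bp of two 1-based inclusive intervals on the same chromosome."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


@dataclass
class CNVRegion:
    """A cross-pool unioned CNV region.

    ``presence`` maps each contributing pool to the set of statuses it
    carries there (normally a single status; a pool can in principle
    contribute both a gain and a loss call to one cluster).  Pools not in
    the map are absent.
    """

    chrom: str
    start: int
    end: int
    presence: dict[str, frozenset[str]] = field(default_factory=dict)
    case_count: int = 0
    control_count: int = 0
    statuses_in_cases: frozenset[str] = frozenset()
    statuses_in_controls: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length_kb(self) -> float:
        return region_length_kb(self.start, self.end)

    @property
    def statuses(self) -> frozenset[str]:
        return self.statuses_in_cases | self.statuses_in_controls

    @property
    def freq_diff(self) -> int:
        return self.case_count - self.control_count

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def filter_min_markers(
    calls: Iterable[CNVCall], p: RegionFilterParams | None = None
) -> list[CNVCall]:
    """Keep calls spanning at least ``min_markers`` markers (default 20)."""
    p = p or RegionFilterParams()
    return [c for c in calls if c.n_markers >= p.min_markers]


def filter_gain_quality(
    calls: Iterable[CNVCall], p: RegionFilterParams | None = None
) -> list[CNVCall]:
    """Drop low-quality gain calls; loss calls pass through untouched.

    A gain call is dropped when its mean LRR is below ``gain_min_mean_lrr``
    (intensity near zero suggests a diploid region) or its LRR SD exceeds
    ``gain_max_sd_lrr`` (too noisy to trust).
    """
    p = p or RegionFilterParams()
    return [
        c
        for c in calls
        if c.status != "gain"
        or (c.mean_lrr >= p.gain_min_mean_lrr and c.sd_lrr <= p.gain_max_sd_lrr)
    ]


def _merge_two(a: CNVCall, b: CNVCall) -> CNVCall:
    # exact pooled mean/SD from the two parts' sufficient statistics;
    # gap markers contribute nothing
    n = a.n_markers + b.n_markers
    mean = (a.n_markers * a.mean_lrr + b.n_markers * b.mean_lrr) / n
    ss = a.n_markers * (a.sd_lrr**2 + a.mean_lrr**2) + b.n_markers * (
        b.sd_lrr**2 + b.mean_lrr**2
    )
    var = max(ss / n - mean**2, 0.0)
    return CNVCall(
        pool_id=a.pool_id,
        chrom=a.chrom,
        start=a.start,
        end=b.end,
        status=a.status,
        n_markers=n,
        mean_lrr=mean,
        sd_lrr=math.sqrt(var),
    )


def merge_gaps(
    calls: Sequence[CNVCall], p: RegionFilterParams | None = None
) -> list[CNVCall]:
    """Merge neighboring same-status calls separated by a small gap.

    For adjacent calls A, B (one pool, one chromosome, sorted,
    non-overlapping) with gap ``g = start(B) − end(A) − 1``, merge when
    ``g / (len(A) + len(B)) < merge_gap_ratio``; the merged call takes part
    in the next comparison.  Calls of different status never merge, and a
    different-status call between two same-status ones blocks their merge.
    """
    p = p or RegionFilterParams()
    calls = sorted(calls, key=lambda c: (c.start, c.end))
    if len(calls) > 1:
        keys = {(c.pool_id, c.chrom) for c in calls}
        if len(keys) > 1:
            raise ValueError("merge_gaps expects calls from one pool and one chromosome")
        for prev, nxt in zip(calls, calls[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlapping calls {prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
    # sweep to a fixed point: merging B with C lengthens B, which can make
    # the A-B gap ratio pass on a later sweep, so one pass is not enough
    while True:
        merged: list[CNVCall] = []
        for call in calls:
            if merged:
                prev = merged[-1]
                gap = call.start - prev.end - 1
                denom = prev.length_bp + call.length_bp
                if call.status == prev.status and gap / denom < p.merge_gap_ratio:
                    merged[-1] = _merge_two(prev, call)
                    continue
            merged.append(call)
        if len(merged) == len(calls):
            return merged
        calls = merged


def union_regions(
    calls_by_pool: Mapping[str, Sequence[CNVCall]], manifest: pd.DataFrame
) -> list[CNVRegion]:
    """Union calls from all pools into disjoint cross-pool regions.

    Per chromosome, overlapping calls (≥1 bp, single linkage) are clustered
    transitively; each cluster becomes one :class:`CNVRegion` spanning the
    cluster's min start to max end, recording which pools carry it and with
    what status.  Raises ``ValueError`` for calls from pools not in the
    manifest.
    """
    groups = dict(zip(manifest["pool_id"], manifest["group"]))
    all_calls: list[CNVCall] = []
    for pool, calls in calls_by_pool.items():
        if pool not in groups:
            raise ValueError(f"pool {pool!r} not in manifest")
        all_calls.extend(calls)

    regions: list[CNVRegion] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in all_calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cluster: list[CNVCall] = []
        cluster_end = -1
        for call in chrom_calls:
            if cluster and call.start > cluster_end:
                regions.append(_region_from_cluster(chrom, cluster, groups))
                cluster = []
            cluster.append(call)
            cluster_end = max(cluster_end, call.end)
        if cluster:
            regions.append(_region_from_cluster(chrom, cluster, groups))
    return regions


def _region_from_cluster(
    chrom: str, cluster: Sequence[CNVCall], groups: Mapping[str, str]
) -> CNVRegion:
    presence: dict[str, set[str]] = {}
    for c in cluster:
        presence.setdefault(c.pool_id, set()).add(c.status)
    frozen = {p: frozenset(s) for p, s in presence.items()}
    case_pools = [p for p in frozen if groups[p] == "case"]
    control_pools = [p for p in frozen if groups[p] == "control"]
    return CNVRegion(
        chrom=chrom,
        start=min(c.start for c in cluster),
        end=max(c.end for c in cluster),
        presence=frozen,
        case_count=len(case_pools),
        control_count=len(control_pools),
        statuses_in_cases=frozenset().union(*(frozen[p] for p in case_pools)) if case_pools else frozenset(),
        statuses_in_controls=frozenset().union(*(frozen[p] for p in control_pools)) if control_pools else frozenset(),
    )


def count_unique_regions(
    calls_by_pool: Mapping[str, Sequence[CNVCall]],
    manifest: pd.DataFrame,
    group: str | None = None,
) -> int:
    """Number of unique regions after union, optionally within one group."""
    if group is not None:
        pools = set(manifest.loc[manifest["group"] == group, "pool_id"])
        calls_by_pool = {p: c for p, c in calls_by_pool.items() if p in pools}
        manifest = manifest.loc[manifest["group"] == group]
    return len(union_regions(calls_by_pool, manifest))
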