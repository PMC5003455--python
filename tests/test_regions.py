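"""Region operations: lengths, filters, gap merging, cross-pool union."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolcnv.config import RegionFilterParams
from poolcnv.regions import (
    filter_gain_quality,
    filter_min_markers,
    merge_gaps,
    overlap,
    region_length_kb,
    union_regions,
)

from conftest import make_call, make_manifest


# ---------------------------------------------------------------- lengths


@pytest.mark.parametrize(
    "start, end, kb",
    [
        (24193894, 24282139, 88.246),  # published loss region, 3-decimal dialect
        (13224130, 13256233, 32.104),  # published gain region, prints as 32.10
        (5, 5, 0.001),  # single base
        (1, 1000, 1.0),
    ],
)
def test_region_length_inclusive(start, end, kb):
    assert region_length_kb(start, end) == pytest.approx(kb)


def test_region_length_rejects_inverted():
    with pytest.raises(ValueError):
        region_length_kb(10, 9)


@pytest.mark.parametrize(
    "a, b, expected",
    [((10, 20), (15, 30), 6), ((10, 20), (21, 30), 0), ((10, 20), (10, 20), 11)],
)
def test_overlap_inclusive_arithmetic(a, b, expected):
    assert overlap(a, b) == expected
    assert overlap(b, a) == expected


# ---------------------------------------------------------------- filters


def test_min_marker_filter_boundary():
    calls = [make_call(1, 100, n_markers=19), make_call(200, 300, n_markers=20)]
    kept = filter_min_markers(calls, RegionFilterParams())
    assert [c.n_markers for c in kept] == [20]
    assert filter_min_markers([], RegionFilterParams()) == []


@pytest.mark.parametrize(
    "status, mean, sd, kept",
    [
        ("gain", 0.015, 0.1, False),  # mean below 0.02
        ("gain", 0.03, 0.25, False),  # sd above 0.2
        ("gain", 0.03, 0.1, True),
        ("gain", 0.02, 0.2, True),  # both exactly at bound survive
        ("loss", -0.5, 0.3, True),  # loss calls are never touched
        ("loss", -0.001, 0.9, True),
    ],
)
def test_gain_quality_filter(status, mean, sd, kept):
    call = make_call(1, 100, status=status, mean_lrr=mean, sd_lrr=sd)
    assert (call in filter_gain_quality([call], RegionFilterParams())) is kept


def test_filters_commute():
    calls = [
        make_call(1, 100, n_markers=10, mean_lrr=0.01),
        make_call(200, 300, n_markers=30, mean_lrr=0.01),
        make_call(400, 500, n_markers=30, mean_lrr=0.05),
        make_call(600, 700, n_markers=5, status="loss", mean_lrr=-0.4),
    ]
    p = RegionFilterParams()
    ab = filter_gain_quality(filter_min_markers(calls, p), p)
    ba = filter_min_markers(filter_gain_quality(calls, p), p)
    assert ab == ba


# ---------------------------------------------------------------- merging


def test_merge_small_gap():
    """100 kb + 100 kb with a 30 kb gap: ratio 0.15 < 0.2 -> one call."""
    a = make_call(1, 100_000, n_markers=40, mean_lrr=0.04, sd_lrr=0.02)
    b = make_call(130_001, 230_000, n_markers=60, mean_lrr=0.06, sd_lrr=0.03)
    (m,) = merge_gaps([a, b], RegionFilterParams())
    assert (m.start, m.end) == (1, 230_000)
    assert m.n_markers == 100  # marker count is conserved; gap has none


def test_no_merge_large_gap():
    """Same calls with a 50 kb gap: ratio 0.25 -> kept separate."""
    a = make_call(1, 100_000)
    b = make_call(150_001, 250_000)
    assert len(merge_gaps([a, b], RegionFilterParams())) == 2


def test_abutting_calls_merge():
    a = make_call(1, 100)
    b = make_call(101, 200)
    assert len(merge_gaps([a, b], RegionFilterParams())) == 1


def test_different_status_never_merges():
    a = make_call(1, 100_000, status="gain")
    b = make_call(100_101, 200_000, status="loss", mean_lrr=-0.3)
    assert len(merge_gaps([a, b], RegionFilterParams())) == 2


def test_merged_call_cascades():
    """A merged call participates in the next comparison."""
    calls = [
        make_call(1, 100_000, n_markers=30),
        make_call(110_001, 210_000, n_markers=30),  # gap 10k / 200k -> merge
        make_call(270_001, 370_000, n_markers=30),  # gap 60k / (310k + 100k) -> merge
    ]
    (m,) = merge_gaps(calls, RegionFilterParams())
    assert (m.start, m.end, m.n_markers) == (1, 370_000, 90)


def test_merge_statistics_exact():
    """Merged mean/SD equal the stats of the concatenated marker LRRs."""
    rng = np.random.default_rng(0)
    x, y = rng.normal(0.05, 0.02, 30), rng.normal(0.07, 0.03, 50)
    a = make_call(1, 1000, n_markers=30, mean_lrr=x.mean(), sd_lrr=x.std())
    b = make_call(1100, 2000, n_markers=50, mean_lrr=y.mean(), sd_lrr=y.std())
    (m,) = merge_gaps([a, b], RegionFilterParams())
    z = np.concatenate([x, y])
    assert m.mean_lrr == pytest.approx(z.mean())
    assert m.sd_lrr == pytest.approx(z.std())


def test_merge_rejects_overlapping_input():
    with pytest.raises(ValueError, match="overlapping"):
        merge_gaps([make_call(1, 100), make_call(50, 200)], RegionFilterParams())


@st.composite
def _call_chain(draw):
    n = draw(st.integers(1, 8))
    calls, pos = [], 1
    for _ in range(n):
        length = draw(st.integers(1, 50_000))
        gap = draw(st.integers(1, 30_000))
        status = draw(st.sampled_from(["gain", "loss"]))
        calls.append(
            make_call(pos, pos + length - 1, status=status,
                      n_markers=draw(st.integers(1, 40)),
                      mean_lrr=draw(st.floats(-0.5, 0.5)), sd_lrr=0.02)
        )
        pos += length + gap
    return calls


@given(_call_chain())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_merge_idempotent_and_conserves_markers(calls):
    p = RegionFilterParams()
    once = merge_gaps(calls, p)
    assert merge_gaps(once, p) == once
    assert sum(c.n_markers for c in once) == sum(c.n_markers for c in calls)


# ---------------------------------------------------------------- union


def _brute_force_union_spans(calls):
    """Transitive-closure clustering by repeated sweeps (independent oracle)."""
    clusters = [[c] for c in calls]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    a.chrom == b.chrom and overlap((a.start, a.end), (b.start, b.end)) > 0
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] += clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (cl[0].chrom, min(c.start for c in cl), max(c.end for c in cl)) for cl in clusters
    )


def test_union_identical_calls_two_pools(manifest):
    calls = {
        "case1": [make_call(100, 200, pool_id="case1")],
        "case2": [make_call(100, 200, pool_id="case2")],
    }
    (region,) = union_regions(calls, manifest)
    assert (region.start, region.end) == (100, 200)
    assert region.case_count == 2 and region.control_count == 0
    assert region.statuses_in_cases == {"gain"}


def test_union_partial_overlap_spans_both(manifest):
    calls = {
        "case1": [make_call(100_000, 200_000, pool_id="case1")],
        "control1": [make_call(150_000, 250_000, pool_id="control1", status="loss",
                               mean_lrr=-0.3)],
    }
    (region,) = union_regions(calls, manifest)
    assert (region.start, region.end) == (100_000, 250_000)
    assert region.case_count == region.control_count == 1
    assert region.statuses_in_cases == {"gain"}
    assert region.statuses_in_controls == {"loss"}


def test_union_one_bp_apart_stays_separate(manifest):
    calls = {
        "case1": [make_call(100, 200, pool_id="case1")],
        "case2": [make_call(202, 300, pool_id="case2")],  # gap of 1 bp at 201
    }
    assert len(union_regions(calls, manifest)) == 2


def test_union_unknown_pool_rejected(manifest):
    with pytest.raises(ValueError, match="not in manifest"):
        union_regions({"mystery": [make_call(1, 10, pool_id="mystery")]}, manifest)


@given(st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_union_matches_transitive_closure_oracle(data):
    manifest = make_manifest()
    pools = list(manifest["pool_id"])
    n = data.draw(st.integers(1, 20))
    calls_by_pool = {p: [] for p in pools}
    flat = []
    for i in range(n):
        start = data.draw(st.integers(1, 5000))
        end = start + data.draw(st.integers(0, 1500))
        pool = data.draw(st.sampled_from(pools))
        chrom = data.draw(st.sampled_from(["1", "2"]))
        c = make_call(start, end, pool_id=pool, chrom=chrom)
        calls_by_pool[pool].append(c)
        flat.append(c)
    regions = union_regions(calls_by_pool, manifest)
    got = sorted((r.chrom, r.start, r.end) for r in regions)
    assert got == _brute_force_union_spans(flat)
    # pool input order must not matter
    reordered = {p: calls_by_pool[p] for p in reversed(pools)}
    regions2 = union_regions(reordered, manifest)
    assert got == sorted((r.chrom, r.start, r.end) for r in regions2)


def test_union_output_regions_disjoint(manifest):
    rng = np.random.default_rng(5)
    calls_by_pool = {p: [] for p in manifest["pool_id"]}
    for _ in range(30):
        pool = rng.choice(manifest["pool_id"])
        start = int(rng.integers(1, 10_000))
        calls_by_pool[pool].append(
            make_call(start, start + int(rng.integers(0, 2000)), pool_id=pool)
        )
    regions = sorted(union_regions(calls_by_pool, manifest), key=lambda r: (r.chrom, r.start))
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom:
            assert a.end < b.start
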