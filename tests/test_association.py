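"""Exact rank-sum test, burden analysis, region signal tests, power."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from poolcnv.association import (
    burden_analysis,
    exact_rank_sum_test,
    power_two_sample_t,
    region_signal_test,
)
from poolcnv.regions import CNVRegion
from poolcnv.simulate import simulate_dataset
from poolcnv.config import SimulationConfig

from conftest import make_call, make_manifest


# ------------------------------------------------------------ exact rank-sum


def _oracle_exact_p(x, y):
    """Independent enumeration: own mid-ranks, explicit tail counting."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # mid-rank of the tie block
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[: len(x)])
    n_le = n_ge = n_tot = 0
    for idx in combinations(range(len(pooled)), len(x)):
        w = sum(ranks[i] for i in idx)
        n_tot += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / n_tot)


@pytest.mark.parametrize(
    "x, y",
    [
        ([3, 4, 5, 4, 3, 5, 4, 4], [2, 3, 2, 3, 2, 2, 3, 3]),  # heavy ties
        ([0.1, 0.5, 0.3, 0.9], [0.2, 0.4, 0.6, 0.8]),
        ([1, 1, 1, 1], [1, 1, 1, 2]),
        ([5, 6, 7], [1, 2, 3, 4]),  # unequal sizes, fully separated
    ],
)
def test_exact_p_matches_enumeration_oracle(x, y):
    assert exact_rank_sum_test(x, y) == pytest.approx(_oracle_exact_p(x, y))


def test_exact_p_matches_scipy_on_tie_free_data():
    """Cross-check against scipy's exact Mann-Whitney when there are no ties."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert exact_rank_sum_test(x, y) == pytest.approx(p_scipy, abs=1e-12)


def test_most_extreme_8v8_p_is_two_over_12870():
    p = exact_rank_sum_test([0.30] * 8, [0.00] * 8)
    assert p == pytest.approx(2 / 12870)


def test_identical_groups_p_is_one():
    assert exact_rank_sum_test([2, 3, 2, 3, 2, 2, 3, 3], [2, 3, 2, 3, 2, 2, 3, 3]) == 1.0


def test_label_swap_leaves_two_sided_p_unchanged():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
    assert exact_rank_sum_test(x, y) == pytest.approx(exact_rank_sum_test(y, x))


def test_exact_test_rejects_degenerate_input():
    with pytest.raises(ValueError):
        exact_rank_sum_test([], [1, 2])
    with pytest.raises(ValueError):
        exact_rank_sum_test(list(range(15)), list(range(15)))


# ------------------------------------------------------------ burden


def test_burden_strata_and_na(manifest):
    calls_by_pool = {p: [] for p in manifest["pool_id"]}
    # gains >= 100 kb in cases only; no losses anywhere
    for p in ("case1", "case2", "case3"):
        calls_by_pool[p] = [make_call(1, 150_000, pool_id=p)]
    result = burden_analysis(calls_by_pool, manifest)
    by_key = {(b.size_min_kb, b.cnv_type): b for b in result}
    gain100 = by_key[(100.0, "gain")]
    assert gain100.n_unique_case == 1 and gain100.n_unique_control == 0
    assert gain100.mean_per_case_pool == pytest.approx(3 / 8)
    assert gain100.p_wilcoxon == pytest.approx(
        exact_rank_sum_test([1, 1, 1, 0, 0, 0, 0, 0], [0] * 8)
    )
    assert math.isnan(by_key[(100.0, "loss")].p_wilcoxon)  # no losses: NA
    assert math.isnan(by_key[(500.0, "both")].p_wilcoxon)  # nothing >= 500 kb


def test_burden_size_threshold_inclusive(manifest):
    calls_by_pool = {p: [] for p in manifest["pool_id"]}
    calls_by_pool["case1"] = [make_call(1, 100_000, pool_id="case1")]  # exactly 100 kb
    result = burden_analysis(calls_by_pool, manifest)
    by_key = {(b.size_min_kb, b.cnv_type): b for b in result}
    assert by_key[(100.0, "gain")].n_unique_case == 1


def test_burden_identical_groups_p_one(manifest):
    calls_by_pool = {
        p: [make_call(1, 150_000, pool_id=p)] for p in manifest["pool_id"]
    }
    result = burden_analysis(calls_by_pool, manifest)
    by_key = {(b.size_min_kb, b.cnv_type): b for b in result}
    assert by_key[(100.0, "both")].p_wilcoxon == 1.0


def test_burden_warns_on_odd_group_sizes():
    manifest = make_manifest(case_pools=["case1"], control_pools=["control1"])
    with pytest.warns(UserWarning, match="8v8"):
        burden_analysis({"case1": [], "control1": []}, manifest)


# ------------------------------------------------------------ signal test


def _flat_region(start, end):
    return CNVRegion(chrom="1", start=start, end=end,
                     presence={"case1": frozenset({"gain"})},
                     case_count=1, control_count=0,
                     statuses_in_cases=frozenset({"gain"}))


def test_region_signal_test_separated_groups():
    ds = simulate_dataset(SimulationConfig(n_markers=60, lrr_noise_sd=0.0, seed=3))
    sig = ds.signals.copy()
    region = _flat_region(sig["position"].iloc[10], sig["position"].iloc[40])
    for p in ds.pools_in_group("case"):
        sig[f"{p}.lrr"] += 0.30
    ds.signals = sig
    res = region_signal_test(region, ds)
    assert res.case_medians == tuple([pytest.approx(0.30)] * 8)
    assert res.p_wilcoxon == pytest.approx(2 / 12870)
    assert math.isnan(res.p_t)  # zero variance within both groups


def test_region_signal_test_all_equal_degenerate():
    ds = simulate_dataset(SimulationConfig(n_markers=60, lrr_noise_sd=0.0, seed=3))
    region = _flat_region(
        ds.signals["position"].iloc[0], ds.signals["position"].iloc[59]
    )
    res = region_signal_test(region, ds)
    assert res.p_wilcoxon == 1.0
    assert math.isnan(res.p_t)


def test_region_signal_test_label_swap_symmetry(null_dataset):
    sig = null_dataset.signals
    region = _flat_region(sig["position"].iloc[5], sig["position"].iloc[100])
    res = region_signal_test(region, null_dataset)
    swapped = type(null_dataset)(
        signals=sig,
        manifest=null_dataset.manifest.assign(
            group=null_dataset.manifest["group"].map(
                {"case": "control", "control": "case"}
            )
        ),
        truth=null_dataset.truth,
    )
    res2 = region_signal_test(region, swapped)
    assert res.p_wilcoxon == pytest.approx(res2.p_wilcoxon)
    assert res.p_t == pytest.approx(res2.p_t)


def test_region_without_markers_rejected(null_dataset):
    region = _flat_region(10**12, 10**12 + 10)
    with pytest.raises(ValueError, match="no markers"):
        region_signal_test(region, null_dataset)


def test_welch_equals_student_with_equal_variances():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 8)
    y = x + 0.4  # identical sample SD by construction
    p_welch = stats.ttest_ind(x, y, equal_var=False).pvalue
    p_student = stats.ttest_ind(x, y, equal_var=True).pvalue
    assert p_welch == pytest.approx(p_student, abs=1e-6)


# ------------------------------------------------------------ power


def test_power_null_equals_alpha():
    assert power_two_sample_t(0.0, 1.0, 8, 0.05) == pytest.approx(0.05)


def test_power_monotone_in_effect_and_n():
    powers_d = [power_two_sample_t(d, 1.0, 8) for d in (0.0, 0.5, 1.0, 2.0)]
    assert powers_d == sorted(powers_d)
    powers_n = [power_two_sample_t(1.0, 1.0, n) for n in (2, 4, 8, 16)]
    assert powers_n == sorted(powers_n)


def test_power_matches_monte_carlo():
    """Analytic noncentral-t power vs a vectorized 20k-rep simulation."""
    delta, sd, n, alpha = 2.0, 1.0, 8, 0.05
    rng = np.random.default_rng(7)
    reps = 20_000
    x = rng.normal(delta, sd, size=(reps, n))
    y = rng.normal(0.0, sd, size=(reps, n))
    p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
    mc_power = float((p < alpha).mean())
    assert power_two_sample_t(delta, sd, n, alpha) == pytest.approx(mc_power, abs=0.015)


def test_power_input_validation():
    with pytest.raises(ValueError):
        power_two_sample_t(1, 1, 8, alpha=0)
    with pytest.raises(ValueError):
        power_two_sample_t(1, 0, 8)
    with pytest.raises(ValueError):
        power_two_sample_t(1, 1, 1)
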