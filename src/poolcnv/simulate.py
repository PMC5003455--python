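"""Synthetic pooled SNP-array data with a known CNV truth set.

The simulator emulates an intensity-array experiment run on DNA pools:
equal amounts of DNA from ``pool_size`` subjects are mixed and assayed as a
single sample, so each probe reports the *pool-average* signal.  At a locus
where ``k`` of the ``n`` pooled subjects carry copy number ``c`` (and the
rest are diploid), the mean pool copy number is

    c_bar = ((n - k) * 2 + k * c) / n

and the expected pool Log R ratio is ``log2(c_bar / 2)`` — exactly zero for
an all-diploid pool, ~+0.029 for one duplication carrier in 25, ~−0.029 for
one hemizygous-deletion carrier in 25.  Gaussian pool-level noise is added
on top, and optional data pathologies (missing signals, zero GC scores,
extreme-intensity artifact probes) are injected so the QC stage has
something to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, TrueCNVEvent

__all__ = ["PooledDataset", "simulate_dataset", "expected_pool_lrr", "pool_signal_columns"]

SEX_CHROMS = frozenset({"X", "Y"})


def pool_signal_columns(pools: Sequence[str], kind: str | None = None) -> list[str]:
    """Column names of the wide signal table for the given pools.

    ``kind`` is one of ``lrr``/``baf``/``gc`` or ``None`` for all three,
    ordered (lrr, baf, gc) within each pool.
    """
    kinds = (kind,) if kind else ("lrr", "baf", "gc")
    return [f"{p}.{k}" for p in pools for k in kinds]


@dataclass
class PooledDataset:
    """A pooled-array dataset: signal matrix, pool manifest and truth set.

    ``signals`` is a wide table with columns ``marker_id``, ``chrom``,
    ``position`` and, per pool, ``<pool>.lrr``, ``<pool>.baf``, ``<pool>.gc``
    (missing values are NaN).  Rows are sorted by (chrom, position).
    ``manifest`` has columns ``pool_id`` and ``group`` (case|control).
    """

    signals: pd.DataFrame
    manifest: pd.DataFrame
    truth: list[TrueCNVEvent] = field(default_factory=list)

    @property
    def pools(self) -> list[str]:
        return list(self.manifest["pool_id"])

    def pools_in_group(self, group: str) -> list[str]:
        return list(self.manifest.loc[self.manifest["group"] == group, "pool_id"])

    def validate(self) -> None:
        expected = ["marker_id", "chrom", "position"] + pool_signal_columns(self.pools)
        if list(self.signals.columns) != expected:
            raise ValueError("signal table columns do not match manifest pools")
        for chrom, sub in self.signals.groupby("chrom", sort=False):
            if not sub["position"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")
        if (self.signals["position"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        bad = set(self.manifest["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown pool groups: {sorted(bad)}")

    def __eq__(self, other: object) -> bool:  # value equality, NaN-aware
        if not isinstance(other, PooledDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.signals, other.signals)
            pd.testing.assert_frame_equal(self.manifest, other.manifest)
        except AssertionError:
            return False
        return self.truth == other.truth


def expected_pool_lrr(copy_number: int, carriers: int, pool_size: int) -> float:
    """Noise-free pool LRR for ``carriers`` subjects at ``copy_number``."""
    if not 0 <= carriers <= pool_size:
        raise ValueError("carriers must be in [0, pool_size]")
    c_bar = ((pool_size - carriers) * 2 + carriers * copy_number) / pool_size
    return float(np.log2(c_bar / 2.0))


def _marker_positions(rng: np.random.Generator, n: int, spacing: float) -> np.ndarray:
    gaps = np.maximum(1, np.round(rng.exponential(spacing, size=n)).astype(np.int64))
    return np.cumsum(gaps)


def _check_event_conflicts(events: Sequence[TrueCNVEvent], pools: Sequence[str]) -> None:
    # Overlapping events are allowed unless a pool carries both with
    # different copy numbers at the shared positions — that is unresolvable.
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.chrom != b.chrom or a.start > b.end or b.start > a.end:
                continue
            if a.copy_number == b.copy_number:
                continue
            for pool in pools:
                if a.carriers_per_pool.get(pool, 0) > 0 and b.carriers_per_pool.get(pool, 0) > 0:
                    raise ValueError(
                        f"events {a.name!r} and {b.name!r} overlap on {a.chrom} with "
                        f"conflicting copy numbers in pool {pool}"
                    )


def simulate_dataset(config: SimulationConfig) -> PooledDataset:
    """Simulate a pooled-array dataset under ``config``; deterministic per seed.

    Returns a :class:`PooledDataset` whose truth set is ``config.events``.
    Raises ``ValueError`` if two events with different copy numbers overlap
    in a pool that carries both.
    """
    pools = config.pools
    _check_event_conflicts(config.events, pools)
    rng = np.random.default_rng(config.seed)

    # --- marker map: split n_markers over autosomes, tail fraction on chrX
    n_sex = int(round(config.n_markers * config.sex_chrom_fraction))
    n_auto = config.n_markers - n_sex
    chrom_labels: list[str] = []
    positions: list[np.ndarray] = []
    n_chroms = len(config.chroms)
    per_chrom = [n_auto // n_chroms + (1 if i < n_auto % n_chroms else 0) for i in range(n_chroms)]
    for chrom, n_c in zip(config.chroms, per_chrom):
        if n_c == 0:
            continue
        chrom_labels += [chrom] * n_c
        positions.append(_marker_positions(rng, n_c, config.marker_spacing))
    if n_sex:
        chrom_labels += ["X"] * n_sex
        positions.append(_marker_positions(rng, n_sex, config.marker_spacing))
    chrom_arr = np.array(chrom_labels)
    pos_arr = np.concatenate(positions)
    n = len(pos_arr)
    n_pools = len(pools)

    # --- mean pool copy number per (marker, pool)
    c_bar = np.full((n, n_pools), 2.0)
    for ev in config.events:
        in_ev = (chrom_arr == ev.chrom) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
        if not in_ev.any():
            continue
        for j, pool in enumerate(pools):
            k = ev.carriers_per_pool.get(pool, 0)
            if k == 0:
                continue
            if k > config.pool_size:
                raise ValueError(f"event {ev.name}: {k} carriers > pool size in {pool}")
            c_bar[in_ev, j] += k * (ev.copy_number - 2) / config.pool_size

    lrr = np.log2(c_bar / 2.0) + rng.normal(0.0, config.lrr_noise_sd, size=(n, n_pools))

    # --- pooled B allele frequency: binomial allele proportion + jitter
    pop_freq = rng.uniform(0.05, 0.95, size=n)
    alleles = 2 * config.pool_size
    baf = rng.binomial(alleles, pop_freq[:, None], size=(n, n_pools)) / alleles
    baf = np.clip(baf + rng.normal(0.0, config.baf_jitter_sd, size=(n, n_pools)), 0.0, 1.0)

    gc = rng.uniform(0.5, 0.95, size=(n, n_pools))

    # --- injected pathologies (each drawn independently for determinism)
    if config.artifact_rate > 0:
        is_artifact = rng.random(n) < config.artifact_rate
        offset = np.where(rng.random(n) < 0.5, 4.0, -8.0)  # beyond the median-LRR QC bounds
        lrr[is_artifact] += offset[is_artifact, None]
    if config.gc_zero_rate > 0:
        gc[rng.random((n, n_pools)) < config.gc_zero_rate] = 0.0
    if config.missing_rate > 0:
        miss = rng.random((n, n_pools)) < config.missing_rate
        lrr[miss] = np.nan
        baf[miss] = np.nan

    order = np.lexsort((pos_arr, chrom_arr))
    data: dict[str, object] = {
        "marker_id": np.array([f"m{i + 1:06d}" for i in range(n)]),
        "chrom": chrom_arr[order],
        "position": pos_arr[order],
    }
    for j, pool in enumerate(pools):
        data[f"{pool}.lrr"] = lrr[order, j]
        data[f"{pool}.baf"] = baf[order, j]
        data[f"{pool}.gc"] = gc[order, j]
    signals = pd.DataFrame(data)
    manifest = pd.DataFrame(
        {
            "pool_id": pools,
            "group": ["case"] * config.n_case_pools + ["control"] * config.n_control_pools,
        }
    )
    ds = PooledDataset(signals=signals, manifest=manifest, truth=list(config.events))
    ds.validate()
    return ds
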