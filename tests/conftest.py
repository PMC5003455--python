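"""Shared fixtures and builders for the poolcnv test suite.

All fixtures are generated programmatically; no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolcnv.caller import CNVCall
from poolcnv.config import SimulationConfig, TrueCNVEvent
from poolcnv.simulate import PooledDataset, simulate_dataset

CASE_POOLS = [f"case{i}" for i in range(1, 9)]
CONTROL_POOLS = [f"control{i}" for i in range(1, 9)]
ALL_POOLS = CASE_POOLS + CONTROL_POOLS


def make_manifest(case_pools=CASE_POOLS, control_pools=CONTROL_POOLS) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pool_id": list(case_pools) + list(control_pools),
            "group": ["case"] * len(case_pools) + ["control"] * len(control_pools),
        }
    )


def make_signals(
    n_markers: int,
    pools=ALL_POOLS,
    chrom: str = "1",
    start: int = 1000,
    spacing: int = 1000,
    lrr: float = 0.0,
    baf: float = 0.5,
    gc: float = 0.8,
) -> pd.DataFrame:
    """A constant-signal marker table: one chromosome, even spacing."""
    data = {
        "marker_id": [f"m{i:05d}" for i in range(n_markers)],
        "chrom": [chrom] * n_markers,
        "position": np.arange(start, start + n_markers * spacing, spacing)[:n_markers],
    }
    for p in pools:
        data[f"{p}.lrr"] = np.full(n_markers, lrr)
        data[f"{p}.baf"] = np.full(n_markers, baf)
        data[f"{p}.gc"] = np.full(n_markers, gc)
    return pd.DataFrame(data)


def make_call(
    start: int,
    end: int,
    pool_id: str = "case1",
    chrom: str = "1",
    status: str = "gain",
    n_markers: int = 25,
    mean_lrr: float = 0.03,
    sd_lrr: float = 0.05,
) -> CNVCall:
    return CNVCall(
        pool_id=pool_id,
        chrom=chrom,
        start=start,
        end=end,
        status=status,
        n_markers=n_markers,
        mean_lrr=mean_lrr,
        sd_lrr=sd_lrr,
    )


@pytest.fixture
def manifest() -> pd.DataFrame:
    return make_manifest()


@pytest.fixture(scope="session")
def null_dataset() -> PooledDataset:
    """A small event-free dataset with moderate noise (seed-fixed)."""
    return simulate_dataset(
        SimulationConfig(n_markers=400, lrr_noise_sd=0.15, seed=11)
    )


@pytest.fixture(scope="session")
def event_dataset() -> PooledDataset:
    """Low-noise dataset with one case-only duplication in three pools."""
    event = TrueCNVEvent(
        chrom="1",
        start=200_000,
        end=320_000,
        copy_number=3,
        carriers_per_pool={"case1": 1, "case2": 1, "case3": 1},
        group="case",
        name="dup_case",
    )
    return simulate_dataset(
        SimulationConfig(
            n_markers=1500, lrr_noise_sd=0.01, marker_spacing=2000, events=[event], seed=7
        )
    )
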