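"""Marker-level quality control for pooled-array signals.

Three filters, applied in a fixed order, each to the survivors of the
previous one:

1. drop markers with any missing signal value in any pool, or located on a
   sex chromosome;
2. drop markers whose GC score is exactly zero in more than
   ``max_gc_zero_pools`` pools (default 3);
3. drop markers whose median Log R ratio across all pools is above 1 or
   below −5 (strict; the median of an even pool count is the mean of the two
   central order statistics).

Each removal is attributed to the first rule that fails, so the report's
counts are additive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCThresholds
from .simulate import SEX_CHROMS, pool_signal_columns

__all__ = [
    "QCReport",
    "filter_missing_and_sex",
    "filter_gc_zero",
    "filter_median_lrr",
    "run_qc",
]


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_sex: int
    n_removed_gc: int
    n_removed_median_lrr: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missing
            + self.n_removed_sex
            + self.n_removed_gc
            + self.n_removed_median_lrr
        )
        if self.n_retained != self.n_input - removed:
            raise ValueError("QCReport counts are inconsistent")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def log_lines(self) -> list[str]:
        return [
            f"markers in: {self.n_input}",
            f"removed, missing signal in >=1 pool: {self.n_removed_missing}",
            f"removed, sex chromosome: {self.n_removed_sex}",
            f"removed, GC score zero in too many pools: {self.n_removed_gc}",
            f"removed, median LRR out of bounds: {self.n_removed_median_lrr}",
            f"markers retained: {self.n_retained}",
        ]


def _is_sex_chrom(chrom: pd.Series) -> pd.Series:
    return chrom.astype(str).str.removeprefix("chr").str.upper().isin(SEX_CHROMS)


def _pools_of(markers: pd.DataFrame) -> list[str]:
    return sorted({c.split(".", 1)[0] for c in markers.columns if c.endswith(".lrr")})


def filter_missing_and_sex(markers: pd.DataFrame) -> pd.DataFrame:
    """Drop markers with any missing LRR/BAF/GC value or on chrX/chrY."""
    pools = _pools_of(markers)
    signal_cols = pool_signal_columns(pools)
    missing = markers[signal_cols].isna().any(axis=1)
    sex = _is_sex_chrom(markers["chrom"])
    return markers.loc[~missing & ~sex]


def filter_gc_zero(markers: pd.DataFrame, t: QCThresholds | None = None) -> pd.DataFrame:
    """Drop markers whose GC score is exactly 0 in more than the allowed pools."""
    t = t or QCThresholds()
    gc_cols = pool_signal_columns(_pools_of(markers), "gc")
    n_zero = (markers[gc_cols] == 0.0).sum(axis=1)
    return markers.loc[n_zero <= t.max_gc_zero_pools]


def filter_median_lrr(markers: pd.DataFrame, t: QCThresholds | None = None) -> pd.DataFrame:
    """Drop markers with median LRR (across all pools) out of (lower, upper)."""
    t = t or QCThresholds()
    lrr_cols = pool_signal_columns(_pools_of(markers), "lrr")
    med = markers[lrr_cols].median(axis=1, skipna=True)
    keep = ~((med > t.median_lrr_upper) | (med < t.median_lrr_lower))
    # all-NaN medians are unanswerable here; the missing-signal rule owns them
    return markers.loc[keep | med.isna()]


def run_qc(
    markers: pd.DataFrame, t: QCThresholds | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the three filters in order and account for every removal."""
    t = t or QCThresholds()
    markers = markers.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    n_input = len(markers)

    step1 = filter_missing_and_sex(markers)
    # split step-1 removals into the two sub-rules; a marker failing both is
    # attributed to the missing-signal rule (first in order) so counts stay additive
    removed1 = markers.loc[~markers.index.isin(step1.index)]
    sig_cols = pool_signal_columns(_pools_of(markers))
    n_missing = int(removed1[sig_cols].isna().any(axis=1).sum()) if len(removed1) else 0
    n_sex = len(removed1) - n_missing

    step2 = filter_gc_zero(step1, t)
    n_gc = len(step1) - len(step2)
    step3 = filter_median_lrr(step2, t)
    n_med = len(step2) - len(step3)

    report = QCReport(
        n_input=n_input,
        n_removed_missing=n_missing,
        n_removed_sex=n_sex,
        n_removed_gc=n_gc,
        n_removed_median_lrr=n_med,
        n_retained=len(step3),
    )
    return step3.reset_index(drop=True), report
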