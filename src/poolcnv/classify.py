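"""Select informative CNV regions by their case/control pattern.

A unioned region is *informative* when its pattern of presence across case
and control pools, combined with whether the region is already catalogued
in a population reference CNV map, matches one of four rules:

- ``different_status``: both groups carry the region but with disjoint
  status sets (e.g. gain in controls, loss in cases);
- ``important_in_cases``: found only in case pools and *not* in the
  reference map (a novel, case-specific region);
- ``important_in_controls``: found only in control pools and *also* in the
  reference map (a known polymorphism that cases conspicuously lack);
- ``enriched_in_cases`` / ``enriched_in_controls``: carried by both groups
  with a pool-frequency difference of at least ``freq_diff_threshold``
  (default 3), direction given by the sign.

Everything else is ``uninformative``.  The status-conflict rule is checked
first; rules 1–3 are mutually exclusive by their count conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import read_bed
from .regions import CNVRegion

__all__ = [
    "ReferenceCNVEntry",
    "ReferenceCNVMap",
    "ClassifiedRegion",
    "CATEGORIES",
    "in_reference_map",
    "classify_region",
    "classify_all",
    "summarize_categories",
]

CATEGORIES = (
    "important_in_cases",
    "important_in_controls",
    "enriched_in_cases",
    "enriched_in_controls",
    "different_status",
    "uninformative",
)


@dataclass(frozen=True)
class ReferenceCNVEntry:
    """One interval of a population CNV map (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    status: str = "unknown"  # gain | loss | unknown
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("reference entry start > end")


class ReferenceCNVMap:
    """Per-chromosome interval index over reference CNV entries."""

    def __init__(self, entries: Iterable[ReferenceCNVEntry] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.entries: list[ReferenceCNVEntry] = []
        for e in entries:
            self.add(e)

    def add(self, entry: ReferenceCNVEntry) -> None:
        self.entries.append(entry)
        tree = self._trees.setdefault(entry.chrom, IntervalTree())
        # intervaltree is half-open; +1 converts the inclusive end
        tree.addi(entry.start, entry.end + 1, entry)

    def overlapping(self, chrom: str, start: int, end: int) -> list[ReferenceCNVEntry]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end + 1)]

    @classmethod
    def from_bed(cls, path) -> "ReferenceCNVMap":
        """Read a BED-like map; the first extra field naming gain/loss is the status."""
        entries = []
        for chrom, start, end, *extra in read_bed(path):
            status = "unknown"
            for f in extra:
                if f.lower() in ("gain", "loss"):
                    status = f.lower()
                    break
            entries.append(ReferenceCNVEntry(chrom, start, end, status=status))
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ClassifiedRegion:
    region: CNVRegion
    category: str
    in_reference: bool
    freq_diff: int  # case_count − control_count

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def in_reference_map(region: CNVRegion, refmap: ReferenceCNVMap) -> bool:
    """True iff any reference entry overlaps the region by >= 1 bp."""
    return bool(refmap.overlapping(region.chrom, region.start, region.end))


def classify_region(
    region: CNVRegion, refmap: ReferenceCNVMap, freq_diff_threshold: int = 3
) -> ClassifiedRegion:
    """Assign exactly one category to a unioned region.

    Raises ``ValueError`` for a region present in no pool (such a region
    cannot come out of the union step).
    """
    nc, nk = region.case_count, region.control_count
    if nc == 0 and nk == 0:
        raise ValueError("region with zero presence in all pools")
    in_ref = in_reference_map(region, refmap)
    diff = nc - nk

    if (
        nc >= 1
        and nk >= 1
        and region.statuses_in_cases
        and region.statuses_in_controls
        and region.statuses_in_cases.isdisjoint(region.statuses_in_controls)
    ):
        category = "different_status"
    elif nk == 0 and nc >= 1 and not in_ref:
        category = "important_in_cases"
    elif nc == 0 and nk >= 1 and in_ref:
        category = "important_in_controls"
    elif nc >= 1 and nk >= 1 and abs(diff) >= freq_diff_threshold:
        category = "enriched_in_cases" if diff > 0 else "enriched_in_controls"
    else:
        category = "uninformative"
    return ClassifiedRegion(region=region, category=category, in_reference=in_ref, freq_diff=diff)


def classify_all(
    regions: Iterable[CNVRegion], refmap: ReferenceCNVMap, freq_diff_threshold: int = 3
) -> list[ClassifiedRegion]:
    return [classify_region(r, refmap, freq_diff_threshold) for r in regions]


def summarize_categories(classified: Sequence[ClassifiedRegion]) -> pd.DataFrame:
    """Per-category region counts with gain/loss breakdown and mean length.

    Returns one row per category (informative categories first, then
    ``uninformative``) plus a ``total_informative`` row summing the five
    informative categories.  A region whose status set contains both gain
    and loss contributes to both breakdown columns.
    """
    rows = []
    for cat in CATEGORIES:
        members = [c for c in classified if c.category == cat]
        n = len(members)
        n_gain = sum(1 for c in members if "gain" in c.region.statuses)
        n_loss = sum(1 for c in members if "loss" in c.region.statuses)
        mean_len = (
            sum(c.region.length_kb for c in members) / n if n else 0.0
        )
        rows.append(
            {"category": cat, "n_regions": n, "n_gain": n_gain, "n_loss": n_loss,
             "mean_length_kb": mean_len}
        )
    informative = [r for r in rows if r["category"] != "uninformative"]
    rows.append(
        {
            "category": "total_informative",
            "n_regions": sum(r["n_regions"] for r in informative),
            "n_gain": sum(r["n_gain"] for r in informative),
            "n_loss": sum(r["n_loss"] for r in informative),
            "mean_length_kb": float("nan"),
        }
    )
    return pd.DataFrame(rows)
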