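"""Gene mapping into CNV regions, candidate-list intersection, and reports.

A gene is mapped to a region when the two intervals overlap by at least one
base pair (partial inclusion counts).  Candidate-list matching is
case-insensitive and honors gene synonyms, since psychiatric candidate
genes are routinely cited under aliases (e.g. ARNTL/BMAL1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .association import BurdenStratum, SignalTestResult
from .classify import ClassifiedRegion
from .io import read_bed
from .regions import CNVRegion

__all__ = [
    "GeneRecord",
    "RegionGeneMap",
    "load_genes_bed",
    "load_candidate_list",
    "map_genes",
    "intersect_candidates",
    "emit_reports",
    "format_length_kb",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval (1-based inclusive) with optional synonyms."""

    name: str
    chrom: str
    start: int
    end: int
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")

    def all_names(self) -> frozenset[str]:
        return self.synonyms | {self.name}


@dataclass
class RegionGeneMap:
    """Genes overlapping each region, with candidate-list flags."""

    genes_by_region: dict[tuple[str, int, int], list[str]] = field(default_factory=dict)
    candidate_flags: dict[str, bool] = field(default_factory=dict)

    def genes_for(self, region: CNVRegion) -> list[str]:
        return self.genes_by_region.get((region.chrom, region.start, region.end), [])

    @property
    def n_mappings(self) -> int:
        """Gene-region pairs (a gene in two regions counts twice)."""
        return sum(len(g) for g in self.genes_by_region.values())

    @property
    def unique_genes(self) -> set[str]:
        return {g for genes in self.genes_by_region.values() for g in genes}

    def flagged_genes(self) -> set[str]:
        return {g for g, flag in self.candidate_flags.items() if flag}


def load_genes_bed(path) -> list[GeneRecord]:
    """Read a BED-like gene file: chrom, start, end, name[, synonyms].

    Synonyms are a comma-separated list in the fifth column.
    """
    genes = []
    for chrom, start, end, *extra in read_bed(path):
        if not extra:
            raise ValueError(f"{path}: gene rows need a name column")
        name = extra[0]
        syns = frozenset(s for s in extra[1].split(",") if s) if len(extra) > 1 else frozenset()
        genes.append(GeneRecord(name=name, chrom=chrom, start=start, end=end, synonyms=syns))
    return genes


def load_candidate_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def map_genes(regions: Sequence[CNVRegion], genes: Sequence[GeneRecord]) -> RegionGeneMap:
    """List, per region, every gene overlapping it by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out = RegionGeneMap()
    for r in regions:
        tree = trees.get(r.chrom)
        hits = sorted(iv.data.name for iv in tree.overlap(r.start, r.end + 1)) if tree else []
        out.genes_by_region[(r.chrom, r.start, r.end)] = hits
    return out


def intersect_candidates(
    gene_map: RegionGeneMap,
    candidate_list: Iterable[str],
    genes: Sequence[GeneRecord] = (),
) -> RegionGeneMap:
    """Flag mapped genes that appear in the candidate list.

    Matching is case-insensitive on the gene name or any synonym (the
    ``genes`` records supply the synonyms).  Duplicate candidate names are
    deduplicated with a warning.
    """
    seen: set[str] = set()
    candidates: set[str] = set()
    for name in candidate_list:
        low = name.lower()
        if low in seen:
            warnings.warn(f"duplicate candidate gene {name!r}; deduplicated", stacklevel=2)
            continue
        seen.add(low)
        candidates.add(low)
    synonyms = {g.name: {s.lower() for s in g.all_names()} for g in genes}
    for gene in gene_map.unique_genes:
        names = synonyms.get(gene, {gene.lower()})
        gene_map.candidate_flags[gene] = bool(names & candidates)
    return gene_map


def format_length_kb(start: int, end: int, decimals: int = 2) -> str:
    """Region length in kb, printed at a fixed number of decimals."""
    return f"{(end - start + 1) / 1000.0:.{decimals}f}"


def _region_key(r: CNVRegion) -> dict:
    return {"chrom": r.chrom, "start": r.start, "end": r.end}


def emit_reports(
    outdir,
    *,
    classified: Sequence[ClassifiedRegion] = (),
    summary: pd.DataFrame | None = None,
    burden: Sequence[BurdenStratum] = (),
    signal_tests: Sequence[SignalTestResult] = (),
    gene_map: RegionGeneMap | None = None,
    qc_report_json: str | None = None,
    seed: int | None = None,
    config_obj: object = None,
    length_decimals: int = 2,
) -> dict[str, Path]:
    """Write deterministic TSV/JSON report files; returns path per report.

    Lengths are printed at ``length_decimals`` decimals (2 for the
    signal-test table dialect, 3 for the literature-comparison dialect).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if classified:
        rows = []
        for c in classified:
            r = c.region
            rows.append(
                {
                    **_region_key(r),
                    "length_kb": format_length_kb(r.start, r.end, length_decimals),
                    "category": c.category,
                    "case_count": r.case_count,
                    "control_count": r.control_count,
                    "statuses": "+".join(sorted(r.statuses)),
                    "in_reference": c.in_reference,
                    "freq_diff": c.freq_diff,
                }
            )
        path = out / "classified_regions.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["classified"] = path

    if summary is not None:
        path = out / "category_summary.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.2f")
        written["summary"] = path

    if burden:
        path = out / "burden.tsv"
        pd.DataFrame([dataclasses.asdict(b) for b in burden]).to_csv(
            path, sep="\t", index=False, na_rep="NA", float_format="%.4g"
        )
        written["burden"] = path

    if signal_tests:
        rows = []
        for t in signal_tests:
            r = t.region
            rows.append(
                {
                    **_region_key(r),
                    "length_kb": format_length_kb(r.start, r.end, length_decimals),
                    "statuses": "+".join(sorted(r.statuses)),
                    "case_count": r.case_count,
                    "control_count": r.control_count,
                    "p_t": "NA" if math.isnan(t.p_t) else f"{t.p_t:.4g}",
                    "p_wilcoxon": f"{t.p_wilcoxon:.4g}",
                }
            )
        path = out / "signal_tests.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["signal_tests"] = path

    if gene_map is not None:
        rows = []
        for (chrom, start, end), genes in sorted(gene_map.genes_by_region.items()):
            for g in genes:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "gene": g,
                        "in_candidate_list": gene_map.candidate_flags.get(g, False),
                    }
                )
        path = out / "region_genes.tsv"
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "in_candidate_list"]).to_csv(
            path, sep="\t", index=False
        )
        written["genes"] = path

    if qc_report_json is not None:
        path = out / "qc_report.json"
        path.write_text(qc_report_json)
        written["qc"] = path

    config_repr = repr(config_obj) if config_obj is not None else ""
    log = {
        "seed": seed,
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest()[:16],
        "n_classified_regions": len(classified),
        "n_signal_tests": len(signal_tests),
        "n_genes_mapped": gene_map.n_mappings if gene_map is not None else 0,
    }
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written["log"] = path
    return written
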