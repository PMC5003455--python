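"""End-to-end orchestration: simulate → QC → call → regions → classify →
associate → annotate → report, with a checkpoint file per stage.

Every stage reads only the previous stage's in-memory output (and writes a
checkpoint under ``outdir``), so two runs with the same configuration and
seed produce byte-identical report bundles.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .annotate import (
    RegionGeneMap,
    emit_reports,
    intersect_candidates,
    load_candidate_list,
    load_genes_bed,
    map_genes,
)
from .association import (
    BurdenStratum,
    SignalTestResult,
    burden_analysis,
    region_signal_test,
)
from .caller import CNVCall, call_all_pools
from .classify import ClassifiedRegion, ReferenceCNVMap, classify_all, summarize_categories
from .config import PipelineConfig
from .qc import QCReport, run_qc
from .regions import (
    CNVRegion,
    count_unique_regions,
    filter_gain_quality,
    filter_min_markers,
    merge_gaps,
    union_regions,
)
from .simulate import PooledDataset, simulate_dataset

__all__ = ["PipelineResult", "run_all", "process_calls"]

log = logging.getLogger("poolcnv")


@dataclass
class PipelineResult:
    dataset: PooledDataset
    qc_markers: pd.DataFrame
    qc_report: QCReport
    calls_by_pool: dict[str, list[CNVCall]]
    regions: list[CNVRegion]
    n_unique_case: int
    n_unique_control: int
    classified: list[ClassifiedRegion]
    burden: list[BurdenStratum]
    signal_tests: list[SignalTestResult]
    gene_map: RegionGeneMap | None
    report_paths: dict[str, Path] = field(default_factory=dict)


def process_calls(
    calls_by_pool: Mapping[str, Sequence[CNVCall]], config: PipelineConfig
) -> dict[str, list[CNVCall]]:
    """Apply the region filters and the gap merge to each pool's calls."""
    p = config.region_filters
    out: dict[str, list[CNVCall]] = {}
    for pool, calls in calls_by_pool.items():
        calls = filter_min_markers(calls, p)
        calls = filter_gain_quality(calls, p)
        merged: list[CNVCall] = []
        by_chrom: dict[str, list[CNVCall]] = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom in sorted(by_chrom):
            merged.extend(merge_gaps(by_chrom[chrom], p))
        out[pool] = merged
    return out


def _write_regions(regions: Sequence[CNVRegion], path: Path) -> None:
    rows = [
        (
            r.chrom, r.start, r.end,
            "+".join(sorted(r.statuses)),
            r.case_count, r.control_count,
            ",".join(f"{p}:{'+'.join(sorted(s))}" for p, s in sorted(r.presence.items())),
        )
        for r in regions
    ]
    pio.write_bed(
        rows, path, columns=("statuses", "case_count", "control_count", "presence")
    )


def run_all(config: PipelineConfig, dataset: PooledDataset | None = None) -> PipelineResult:
    """Run every stage under ``config``; returns all stage outputs.

    ``dataset`` overrides the simulation stage (e.g. data re-read from
    disk).  Stage failures propagate as exceptions naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if dataset is None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            dataset = simulate_dataset(sim_cfg)
        pio.write_dataset(dataset, outdir / "dataset")
        log.info("simulated %d markers x %d pools", len(dataset.signals), len(dataset.pools))

        stage = "qc"
        qc_markers, qc_report = run_qc(dataset.signals, config.qc)
        for line in qc_report.log_lines():
            log.info("qc: %s", line)

        stage = "call"
        raw_calls = call_all_pools(dataset, config.hmm, markers=qc_markers)
        pio.write_calls_bed(raw_calls, outdir / "calls_raw.bed")

        stage = "regions"
        calls = process_calls(raw_calls, config)
        pio.write_calls_bed(calls, outdir / "calls_filtered.bed")
        regions = union_regions(calls, dataset.manifest)
        _write_regions(regions, outdir / "regions.bed")
        n_uc = count_unique_regions(calls, dataset.manifest, "case")
        n_uk = count_unique_regions(calls, dataset.manifest, "control")
        log.info("regions: %d cross-pool, %d case-unique, %d control-unique",
                 len(regions), n_uc, n_uk)

        stage = "classify"
        refmap = (
            ReferenceCNVMap.from_bed(config.refmap_path)
            if config.refmap_path
            else ReferenceCNVMap()
        )
        classified = classify_all(regions, refmap, config.freq_diff_threshold)
        summary = summarize_categories(classified)

        stage = "associate"
        burden = burden_analysis(calls, dataset.manifest)
        informative = [c for c in classified if c.category != "uninformative"]
        signal_tests = []
        for c in informative:
            try:
                signal_tests.append(region_signal_test(c.region, dataset, qc_markers))
            except ValueError:
                pass  # region with no QC-retained markers: nothing to test

        stage = "annotate"
        gene_map = None
        if config.genes_path:
            genes = load_genes_bed(config.genes_path)
            gene_map = map_genes([c.region for c in informative], genes)
            if config.candidates_path:
                gene_map = intersect_candidates(
                    gene_map, load_candidate_list(config.candidates_path), genes
                )

        stage = "report"
        report_paths = emit_reports(
            outdir,
            classified=classified,
            summary=summary,
            burden=burden,
            signal_tests=signal_tests,
            gene_map=gene_map,
            qc_report_json=qc_report.to_json(),
            seed=config.seed,
            # hash the analysis parameters, not the output location
            config_obj=dataclasses.replace(config, outdir=""),
        )
    except Exception:
        print(f"pipeline failed at stage: {stage}", file=sys.stderr)
        raise
    return PipelineResult(
        dataset=dataset,
        qc_markers=qc_markers,
        qc_report=qc_report,
        calls_by_pool=calls,
        regions=regions,
        n_unique_case=n_uc,
        n_unique_control=n_uk,
        classified=classified,
        burden=burden,
        signal_tests=signal_tests,
        gene_map=gene_map,
        report_paths=report_paths,
    )
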