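"""Configuration and parameter types for the pooled-CNV pipeline.

All genomic coordinates are 1-based inclusive in memory; BED-like files on
disk are 0-based half-open and converted at I/O time (see :mod:`poolcnv.io`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "TrueCNVEvent",
    "SimulationConfig",
    "QCThresholds",
    "HMMParams",
    "RegionFilterParams",
    "PipelineConfig",
    "load_pipeline_config",
]


@dataclass(frozen=True)
class TrueCNVEvent:
    """A ground-truth CNV embedded by the simulator.

    ``carriers_per_pool`` maps pool id to the number of carrier subjects in
    that pool; pools not listed have zero carriers.  ``copy_number`` is the
    carrier copy number (0, 1 for losses; 3, 4 for gains — never the diploid
    2).  Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    carriers_per_pool: Mapping[str, int] = field(default_factory=dict)
    group: str = "both"  # case | control | both; bookkeeping label only
    name: str = "event"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"event {self.name}: start {self.start} > end {self.end}")
        if self.copy_number == 2 or self.copy_number not in (0, 1, 3, 4):
            raise ValueError(f"event {self.name}: copy_number must be in {{0,1,3,4}}")
        if self.group not in ("case", "control", "both"):
            raise ValueError(f"event {self.name}: bad group {self.group!r}")
        for pool, k in self.carriers_per_pool.items():
            if k < 0:
                raise ValueError(f"event {self.name}: negative carriers in {pool}")

    @property
    def status(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"


@dataclass
class SimulationConfig:
    """Study design and noise model for the pooled-array simulator.

    Defaults mirror the pooling design the pipeline targets: 8 case and
    8 control pools of 25 subjects each, with pool-level Log R ratio noise
    (SD 0.15) chosen so a single duplication carrier in a pool (LRR shift
    ≈ +0.029) sits near the detection edge.
    """

    n_markers: int = 2000
    n_case_pools: int = 8
    n_control_pools: int = 8
    pool_size: int = 25
    marker_spacing: float = 2500.0  # mean inter-marker distance, bp
    lrr_noise_sd: float = 0.15  # pool-level, dimensionless
    baf_jitter_sd: float = 0.01
    missing_rate: float = 0.0  # per marker/pool cell
    gc_zero_rate: float = 0.0  # per marker/pool cell
    artifact_rate: float = 0.0  # per marker: extreme-intensity probe
    sex_chrom_fraction: float = 0.0  # fraction of markers placed on chrX
    chroms: Sequence[str] = ("1",)  # autosomal chromosome labels
    events: Sequence[TrueCNVEvent] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_markers", "n_case_pools", "n_control_pools", "pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("missing_rate", "gc_zero_rate", "artifact_rate", "sex_chrom_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.lrr_noise_sd < 0:
            raise ValueError("lrr_noise_sd must be >= 0")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")

    @property
    def case_pools(self) -> list[str]:
        return [f"case{i + 1}" for i in range(self.n_case_pools)]

    @property
    def control_pools(self) -> list[str]:
        return [f"control{i + 1}" for i in range(self.n_control_pools)]

    @property
    def pools(self) -> list[str]:
        return self.case_pools + self.control_pools


@dataclass
class QCThresholds:
    """Marker-level QC cutoffs.

    A marker is dropped when its GC score is exactly zero in more than
    ``max_gc_zero_pools`` pools, or when its median Log R ratio across all
    pools is above ``median_lrr_upper`` or below ``median_lrr_lower``
    (strict inequalities; markers exactly at a bound are retained).
    """

    max_gc_zero_pools: int = 3
    median_lrr_upper: float = 1.0
    median_lrr_lower: float = -5.0

    def __post_init__(self) -> None:
        if self.max_gc_zero_pools < 0:
            raise ValueError("max_gc_zero_pools must be >= 0")
        if self.median_lrr_lower >= self.median_lrr_upper:
            raise ValueError("median_lrr_lower must be < median_lrr_upper")


@dataclass
class HMMParams:
    """Parameters of the three-state (loss/normal/gain) segmentation HMM.

    Emission means are on the pooled-LRR scale, where a one-in-25 carrier
    shifts the pool mean by ~±0.03.  ``emission_sd`` of ``None`` means
    "estimate per pool by MAD".  ``switch_prob`` is the per-marker
    probability of moving to each of the two other states.
    """

    loss_mean: float = -0.03
    normal_mean: float = 0.0
    gain_mean: float = 0.03
    emission_sd: float | None = None
    switch_prob: float = 1e-4
    min_state_prob: float = 1e-300  # numerical floor, log-space guard

    def __post_init__(self) -> None:
        if not self.loss_mean < self.normal_mean < self.gain_mean:
            raise ValueError("emission means must satisfy loss < normal < gain")
        if not 0.0 < self.switch_prob < 0.5:
            raise ValueError("switch_prob must be in (0, 0.5)")
        if self.emission_sd is not None and self.emission_sd <= 0:
            raise ValueError("emission_sd must be > 0")


@dataclass
class RegionFilterParams:
    """Post-calling region filters and the gap-merge threshold.

    Calls with fewer than ``min_markers`` markers are discarded; gain calls
    with mean LRR below ``gain_min_mean_lrr`` or LRR SD above
    ``gain_max_sd_lrr`` are discarded (loss calls are untouched); adjacent
    same-status calls merge when gap / (len_A + len_B) < ``merge_gap_ratio``.
    """

    min_markers: int = 20
    gain_min_mean_lrr: float = 0.02
    gain_max_sd_lrr: float = 0.2
    merge_gap_ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        if not 0.0 < self.merge_gap_ratio < 1.0:
            raise ValueError("merge_gap_ratio must be in (0, 1)")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serializable)."""

    outdir: str = "results/pipeline"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    hmm: HMMParams = field(default_factory=HMMParams)
    region_filters: RegionFilterParams = field(default_factory=RegionFilterParams)
    freq_diff_threshold: int = 3
    screen_p: float = 0.2  # screening threshold for reporting regions
    significant_p: float = 0.05
    refmap_path: str | None = None
    genes_path: str | None = None
    candidates_path: str | None = None
    seed: int = 0


def _dataclass_from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", {})
    events = [
        _dataclass_from_dict(TrueCNVEvent, ev) for ev in sim.pop("events", [])
    ]
    cfg = PipelineConfig(
        simulation=dataclasses.replace(
            _dataclass_from_dict(SimulationConfig, sim), events=events
        ),
        qc=_dataclass_from_dict(QCThresholds, raw.pop("qc", {})),
        hmm=_dataclass_from_dict(HMMParams, raw.pop("hmm", {})),
        region_filters=_dataclass_from_dict(
            RegionFilterParams, raw.pop("region_filters", {})
        ),
        **raw,
    )
    return cfg
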