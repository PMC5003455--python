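"""The demo pooled-CNV study shared by the numbered analysis scripts.

A 16-pool case/control design (8 + 8 pools of 25 subjects) on one ~12 Mb
synthetic chromosome with ~6000 markers, pool-level LRR noise SD 0.05, and
five embedded CNV events chosen to exercise every informative-region
category plus the single-carrier detection edge:

  dup_case_novel     gain, 3 carriers/pool in case1-3, not in the reference
                     map -> should come out important_in_cases
  del_control_known  loss, 4 carriers/pool in control1-2, present in the
                     reference map -> important_in_controls
  dup_enriched_case  gain, 3 carriers/pool in case1-5 and control1 ->
                     enriched_in_cases (pool-frequency difference 4)
  mixed_status       gain in control3 / loss in case4 at one locus ->
                     different_status
  dup_single_carrier gain, ONE carrier in case6 (pool-LRR shift +0.029,
                     below the noise floor at SD 0.05) -> expected to be
                     missed; the cost of pooling, on display

All numbers here are the demo's own choices; the package defaults are not
changed by them.  Gene coordinates are synthetic; gene names are real
psychiatric-candidate symbols used for flavor only.
"""

from pathlib import Path

from poolcnv.config import PipelineConfig, SimulationConfig, TrueCNVEvent
from poolcnv.config import HMMParams

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "analysis" / "data"
OUT = ROOT / "results" / "analysis"

SEED = 1234

EVENTS = [
    TrueCNVEvent("1", 1_000_000, 1_200_000, 3,
                 {f"case{i}": 3 for i in (1, 2, 3)}, "case", "dup_case_novel"),
    TrueCNVEvent("1", 3_000_000, 3_200_000, 1,
                 {f"control{i}": 4 for i in (1, 2)}, "control", "del_control_known"),
    TrueCNVEvent("1", 5_000_000, 5_200_000, 3,
                 {**{f"case{i}": 3 for i in (1, 2, 3, 4, 5)}, "control1": 3},
                 "both", "dup_enriched_case"),
    TrueCNVEvent("1", 7_000_000, 7_200_000, 3, {"control3": 3}, "control",
                 "mixed_status_gain"),
    TrueCNVEvent("1", 7_000_000, 7_200_000, 1, {"case4": 4}, "case",
                 "mixed_status_loss"),
    TrueCNVEvent("1", 9_000_000, 9_200_000, 3, {"case6": 1}, "case",
                 "dup_single_carrier"),
]

SIMULATION = SimulationConfig(
    n_markers=6000,
    marker_spacing=2000,
    lrr_noise_sd=0.05,
    missing_rate=0.002,
    gc_zero_rate=0.01,
    artifact_rate=0.002,
    sex_chrom_fraction=0.03,
    events=EVENTS,
    seed=SEED,
)

# reference map: covers del_control_known plus two loci the study never calls
REFMAP = [
    ("1", 2_950_000, 3_250_000, "ref_del", "loss"),
    ("1", 2_000_000, 2_050_000, "ref_other1", "gain"),
    ("1", 11_000_000, 11_100_000, "ref_other2", "gain"),
]

# synthetic gene coordinates; candidate symbols get flagged downstream
GENES = [
    ("1", 1_050_000, 1_120_000, "ARNTL", "BMAL1,MOP3"),
    ("1", 3_020_000, 3_100_000, "DMGDH", ""),
    ("1", 5_050_000, 5_150_000, "PTPRG", ""),
    ("1", 7_080_000, 7_110_000, "TIMP3", ""),
    ("1", 10_500_000, 10_600_000, "NOCAND", ""),
]

CANDIDATES = ["ARNTL", "PTPRG", "SYN3"]

HMM = HMMParams(emission_sd=None)  # per-pool MAD noise estimate


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        outdir=str(OUT / "pipeline"),
        simulation=SIMULATION,
        hmm=HMM,
        refmap_path=str(DATA / "refmap.bed"),
        genes_path=str(DATA / "genes.bed"),
        candidates_path=str(DATA / "candidates.txt"),
        seed=SEED,
    )
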