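"""Association testing: CNV burden per stratum (status x minimum size) and
per-region pooled-signal tests (median LRR per pool, Welch t + exact
8-vs-8 Wilcoxon), plus the power of the signal comparison at a given
effect size."""

import dataclasses

import pandas as pd

from poolcnv.association import burden_analysis, power_two_sample_t, region_signal_test
from poolcnv.classify import ReferenceCNVMap, classify_all
from poolcnv.io import read_calls_bed, read_dataset
from poolcnv.regions import union_regions

from study import DATA, OUT


def main() -> None:
    ds = read_dataset(DATA)
    markers = pd.read_csv(OUT / "markers_qc.tsv", sep="\t", dtype={"chrom": str})
    calls = read_calls_bed(OUT / "calls_filtered.bed", pools=ds.pools)

    burden = burden_analysis(calls, ds.manifest)
    pd.DataFrame([dataclasses.asdict(b) for b in burden]).to_csv(
        OUT / "burden.tsv", sep="\t", index=False, na_rep="NA", float_format="%.4g"
    )
    print("burden (size >= kb, type, unique case/control, mean per pool, p):")
    for b in burden:
        print(f"  >={b.size_min_kb:.0f}kb {b.cnv_type:5s} "
              f"{b.n_unique_case}/{b.n_unique_control} "
              f"{b.mean_per_case_pool:.3f}/{b.mean_per_control_pool:.3f} "
              f"p={b.p_wilcoxon:.3g}")

    regions = union_regions(calls, ds.manifest)
    refmap = ReferenceCNVMap.from_bed(DATA / "refmap.bed")
    informative = [c for c in classify_all(regions, refmap)
                   if c.category != "uninformative"]
    print("\nper-region signal tests (informative regions):")
    rows = []
    for c in informative:
        t = region_signal_test(c.region, ds, markers)
        rows.append(t)
        r = c.region
        print(f"  {r.chrom}:{r.start}-{r.end} {c.category}: "
              f"p_t={t.p_t:.4g} p_wilcoxon={t.p_wilcoxon:.4g}")
    delta_sd = 2.0
    print(f"\npower to detect a {delta_sd} SD median-LRR shift with 8v8 pools: "
          f"{power_two_sample_t(delta_sd, 1.0, 8):.3f}")


if __name__ == "__main__":
    main()
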