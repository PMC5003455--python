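"""Define CNV regions: drop short (<20 marker) and low-quality gain calls,
merge neighbors across small gaps (< 0.2 gap ratio), then union across all
16 pools into comparable cross-pool regions."""

from poolcnv.io import read_calls_bed, read_dataset, write_calls_bed
from poolcnv.pipeline import process_calls
from poolcnv.regions import count_unique_regions, union_regions

from study import DATA, OUT, pipeline_config


def main() -> None:
    ds = read_dataset(DATA)
    raw = read_calls_bed(OUT / "calls_raw.bed", pools=ds.pools)
    n_raw = sum(len(v) for v in raw.values())
    calls = process_calls(raw, pipeline_config())
    n_kept = sum(len(v) for v in calls.values())
    write_calls_bed(calls, OUT / "calls_filtered.bed")

    regions = union_regions(calls, ds.manifest)
    print(f"{n_raw} raw calls -> {n_kept} after filters and gap merge")
    print(f"{len(regions)} cross-pool regions "
          f"({count_unique_regions(calls, ds.manifest, 'case')} unique in case pools, "
          f"{count_unique_regions(calls, ds.manifest, 'control')} in control pools)")
    for r in regions:
        print(f"  {r.chrom}:{r.start}-{r.end} {'+'.join(sorted(r.statuses))} "
              f"cases={r.case_count} controls={r.control_count}")


if __name__ == "__main__":
    main()
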