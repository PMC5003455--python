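"""Classify the unioned regions against the reference CNV map into the
informative categories (case-only novel, control-only known, enriched,
status conflict) and summarize the category table."""

from poolcnv.classify import ReferenceCNVMap, classify_all, summarize_categories
from poolcnv.io import read_calls_bed, read_dataset
from poolcnv.regions import union_regions

from study import DATA, OUT


def main() -> None:
    ds = read_dataset(DATA)
    calls = read_calls_bed(OUT / "calls_filtered.bed", pools=ds.pools)
    regions = union_regions(calls, ds.manifest)
    refmap = ReferenceCNVMap.from_bed(DATA / "refmap.bed")
    classified = classify_all(regions, refmap)
    summary = summarize_categories(classified)
    summary.to_csv(OUT / "category_summary.tsv", sep="\t", index=False,
                   float_format="%.2f")
    print(summary.to_string(index=False))
    for c in classified:
        r = c.region
        print(f"  {r.chrom}:{r.start}-{r.end} -> {c.category} "
              f"(in_reference={c.in_reference}, freq_diff={c.freq_diff:+d})")


if __name__ == "__main__":
    main()
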