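"""Marker QC: drop missing-signal/sex-chromosome markers, failed probes
(GC score 0 in >3 pools) and extreme-intensity artifacts (median LRR >1 or
<-5), reporting how many markers each rule removed."""

from poolcnv.io import read_dataset
from poolcnv.qc import run_qc

from study import DATA, OUT


def main() -> None:
    ds = read_dataset(DATA)
    retained, report = run_qc(ds.signals)
    retained.to_csv(OUT / "markers_qc.tsv", sep="\t", index=False, na_rep="NA")
    (OUT / "qc_report.json").write_text(report.to_json())
    for line in report.log_lines():
        print(line)


if __name__ == "__main__":
    main()
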