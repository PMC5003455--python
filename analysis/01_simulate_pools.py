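"""Simulate the demo pooled-array study and write its inputs to disk.

Writes the signal matrix, pool manifest and truth set plus the reference
CNV map, gene annotation and candidate-gene list that the later stages
consume.  Everything is seeded; rerunning reproduces the files byte for
byte.
"""

from poolcnv.io import write_bed, write_dataset
from poolcnv.simulate import simulate_dataset

from study import CANDIDATES, DATA, GENES, REFMAP, SIMULATION


def main() -> None:
    ds = simulate_dataset(SIMULATION)
    write_dataset(ds, DATA)
    write_bed(REFMAP, DATA / "refmap.bed", columns=("name", "status"))
    write_bed(GENES, DATA / "genes.bed", columns=("name", "synonyms"))
    (DATA / "candidates.txt").write_text("\n".join(CANDIDATES) + "\n")

    n_sex = int((ds.signals["chrom"] == "X").sum())
    print(f"wrote {len(ds.signals)} markers x {len(ds.pools)} pools -> {DATA}")
    print(f"  {n_sex} markers on chrX (QC fodder), "
          f"{len(ds.truth)} embedded truth events:")
    for ev in ds.truth:
        pools = ",".join(sorted(ev.carriers_per_pool))
        print(f"  {ev.name}: {ev.chrom}:{ev.start}-{ev.end} CN={ev.copy_number} "
              f"carriers in {pools}")


if __name__ == "__main__":
    main()
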