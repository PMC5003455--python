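"""Segment each pool's Log R ratio into gain/loss calls with the 3-state
HMM, estimating every pool's noise level robustly (MAD) from its own data."""

import pandas as pd

from poolcnv.caller import call_all_pools, estimate_noise
from poolcnv.io import read_dataset, write_calls_bed

from study import DATA, HMM, OUT


def main() -> None:
    ds = read_dataset(DATA)
    markers = pd.read_csv(OUT / "markers_qc.tsv", sep="\t", dtype={"chrom": str})
    calls = call_all_pools(ds, HMM, markers=markers)
    write_calls_bed(calls, OUT / "calls_raw.bed")
    total = sum(len(v) for v in calls.values())
    print(f"{total} raw calls across {len(calls)} pools "
          f"(noise SD estimates {estimate_noise(markers, 'case1'):.3f}..."
          f"{estimate_noise(markers, 'control8'):.3f})")
    for pool in sorted(calls):
        if calls[pool]:
            spans = ", ".join(f"{c.chrom}:{c.start}-{c.end}({c.status})"
                              for c in calls[pool])
            print(f"  {pool}: {spans}")


if __name__ == "__main__":
    main()
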