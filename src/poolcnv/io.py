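"""On-disk formats: signal-matrix TSV, pool manifest, BED-like interval files.

In-memory coordinates are 1-based inclusive; every BED-like file written here
uses the conventional 0-based half-open coordinates (start − 1, end), and the
readers convert back.  Missing signal values are written as ``NA``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import TrueCNVEvent
from .simulate import PooledDataset, pool_signal_columns

__all__ = [
    "ParseError",
    "write_dataset",
    "read_dataset",
    "write_bed",
    "read_bed",
    "write_truth_bed",
    "read_truth_bed",
    "write_calls_bed",
    "read_calls_bed",
]

SIGNALS_FILE = "signals.tsv"
MANIFEST_FILE = "pools.tsv"
TRUTH_FILE = "truth.bed"


class ParseError(ValueError):
    """A malformed input file; message names the file and 1-based line number."""

    def __init__(self, path: str | os.PathLike, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_dataset(ds: PooledDataset, path: str | os.PathLike) -> None:
    """Write signals, manifest and truth set under directory ``path``."""
    ds.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(ds.signals, out / SIGNALS_FILE)
    _write_tsv(ds.manifest, out / MANIFEST_FILE)
    write_truth_bed(ds.truth, out / TRUTH_FILE)


def read_dataset(path: str | os.PathLike) -> PooledDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`ParseError` (with a line number) on malformed content,
    including positions that are not sorted within a chromosome.
    """
    root = Path(path)
    sig_path = root / SIGNALS_FILE
    signals = pd.read_csv(sig_path, sep="\t", dtype={"chrom": str})
    for col in ("marker_id", "chrom", "position"):
        if col not in signals.columns:
            raise ParseError(sig_path, 1, f"missing required column {col!r}")
    # line number = data row index + 2 (header is line 1)
    if (signals["position"] <= 0).any():
        row = int(np.argmax(signals["position"].to_numpy() <= 0))
        raise ParseError(sig_path, row + 2, "position must be positive")
    for chrom, sub in signals.groupby("chrom", sort=False):
        pos = sub["position"].to_numpy()
        bad = np.nonzero(np.diff(pos) < 0)[0]
        if bad.size:
            row = int(sub.index[bad[0] + 1])
            raise ParseError(
                sig_path, row + 2, f"positions not sorted on chromosome {chrom}"
            )
    manifest = pd.read_csv(root / MANIFEST_FILE, sep="\t", dtype=str)
    truth = read_truth_bed(root / TRUTH_FILE) if (root / TRUTH_FILE).exists() else []
    ds = PooledDataset(signals=signals, manifest=manifest, truth=truth)
    try:
        ds.validate()
    except ValueError as exc:
        raise ParseError(sig_path, 1, str(exc)) from exc
    return ds


def write_bed(
    intervals: Iterable[tuple], path: str | os.PathLike, columns: Sequence[str] = ()
) -> None:
    """Write (chrom, start, end, *extra) 1-based inclusive intervals as BED.

    ``columns`` names the extra fields (after the three coordinates).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        header = ["chrom", "start", "end", *columns]
        fh.write("#" + "\t".join(header) + "\n")
        for iv in intervals:
            chrom, start, end, *extra = iv
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
            fields = [str(chrom), str(start - 1), str(end), *map(str, extra)]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    """Read a BED-like file back to 1-based inclusive tuples (chrom, start, end, *extra)."""
    out: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected at least 3 tab-separated fields")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end0 <= start0:
                raise ParseError(path, lineno, f"empty or inverted interval {start0}-{end0}")
            out.append((fields[0], start0 + 1, end0, *fields[3:]))
    return out


def write_truth_bed(events: Sequence[TrueCNVEvent], path: str | os.PathLike) -> None:
    rows = []
    for ev in events:
        carriers = ";".join(f"{p}:{k}" for p, k in sorted(ev.carriers_per_pool.items()))
        rows.append((ev.chrom, ev.start, ev.end, ev.name, ev.copy_number, ev.group, carriers))
    write_bed(rows, path, columns=("name", "copy_number", "group", "carriers"))


def read_truth_bed(path: str | os.PathLike) -> list[TrueCNVEvent]:
    events = []
    for chrom, start, end, *extra in read_bed(path):
        if len(extra) != 4:
            raise ParseError(path, 1, "truth file needs name/copy_number/group/carriers columns")
        name, cn, group, carriers = extra
        carriers_map = {}
        if carriers:
            for item in carriers.split(";"):
                pool, k = item.split(":")
                carriers_map[pool] = int(k)
        events.append(
            TrueCNVEvent(
                chrom=chrom,
                start=start,
                end=end,
                copy_number=int(cn),
                carriers_per_pool=carriers_map,
                group=group,
                name=name,
            )
        )
    return events


def write_calls_bed(calls_by_pool, path: str | os.PathLike) -> None:
    """Write per-pool CNV calls as a BED-like table (one row per call)."""
    rows = [
        (c.chrom, c.start, c.end, c.pool_id, c.status, c.n_markers,
         f"{c.mean_lrr:.6g}", f"{c.sd_lrr:.6g}")
        for pool in sorted(calls_by_pool)
        for c in calls_by_pool[pool]
    ]
    write_bed(rows, path, columns=("pool_id", "status", "n_markers", "mean_lrr", "sd_lrr"))


def read_calls_bed(path: str | os.PathLike, pools: Sequence[str] = ()) -> dict:
    """Read calls back into a pool -> list-of-CNVCall map.

    ``pools`` pre-seeds empty entries so pools without calls still appear.
    """
    from .caller import CNVCall

    out: dict[str, list[CNVCall]] = {p: [] for p in pools}
    for chrom, start, end, *extra in read_bed(path):
        if len(extra) != 5:
            raise ParseError(path, 1, "call rows need pool/status/n_markers/mean/sd columns")
        pool, status, n_markers, mean_lrr, sd_lrr = extra
        out.setdefault(pool, []).append(
            CNVCall(
                pool_id=pool, chrom=chrom, start=start, end=end, status=status,
                n_markers=int(n_markers), mean_lrr=float(mean_lrr),
                sd_lrr=float(sd_lrr),
            )
        )
    return out
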