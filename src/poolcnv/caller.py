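"""Per-pool CNV segmentation of pooled Log R ratio.

A deliberately small three-state hidden Markov model (loss / normal / gain)
with Gaussian emissions on the pool-level LRR and a time-homogeneous,
distance-independent transition matrix.  This is a documented simplification
of the individual-level HMM callers commonly used on array data (which model
six copy-number states, use BAF jointly with LRR, and scale transition
probabilities with inter-marker distance): at pool level the BAF of a
1-in-25 carrier is nearly uninformative, and downstream logic needs only the
gain/normal/loss status, so three LRR-only states suffice.

Segments are maximal runs of a single non-normal state; their coordinates
are the positions of the first and last marker in the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HMMParams
from .simulate import PooledDataset

__all__ = ["CNVCall", "estimate_noise", "viterbi_segment", "call_all_pools", "STATES"]

STATES = ("loss", "normal", "gain")
_LOSS, _NORMAL, _GAIN = 0, 1, 2


@dataclass(frozen=True)
class CNVCall:
    """One called segment in one pool (1-based inclusive coordinates).

    ``mean_lrr``/``sd_lrr`` are computed over the pool's LRR at the
    segment's markers; the SD of a single-marker segment is 0.
    """

    pool_id: str
    chrom: str
    start: int
    end: int
    status: str  # gain | loss
    n_markers: int
    mean_lrr: float
    sd_lrr: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("call start > end")
        if self.status not in ("gain", "loss"):
            raise ValueError(f"bad call status {self.status!r}")
        if self.n_markers < 1:
            raise ValueError("call must span >= 1 marker")
        if not self.sd_lrr >= 0:
            raise ValueError("sd_lrr must be >= 0")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def estimate_noise(markers: pd.DataFrame, pool: str) -> float:
    """Robust pool noise scale: MAD of the pool's LRR times 1.4826."""
    lrr = markers[f"{pool}.lrr"].to_numpy(dtype=float)
    lrr = lrr[np.isfinite(lrr)]
    if lrr.size < 10:
        raise ValueError(f"need >= 10 finite LRR values to estimate noise for {pool}")
    mad = np.median(np.abs(lrr - np.median(lrr)))
    return float(mad * 1.4826)


def _log_transition_matrix(switch_prob: float) -> np.ndarray:
    q = switch_prob
    trans = np.full((3, 3), q)
    np.fill_diagonal(trans, 1.0 - 2.0 * q)
    return np.log(trans)


def _log_emissions(lrr: np.ndarray, params: HMMParams, sd: float) -> np.ndarray:
    means = np.array([params.loss_mean, params.normal_mean, params.gain_mean])
    resid = lrr[:, None] - means[None, :]
    return -0.5 * np.log(2.0 * np.pi * sd * sd) - 0.5 * (resid / sd) ** 2


def _viterbi_path(lrr: np.ndarray, params: HMMParams, sd: float) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    n = lrr.size
    log_trans = _log_transition_matrix(params.switch_prob)
    log_emit = _log_emissions(lrr, params, sd)
    # initial distribution: one transition step out of the normal state
    log_pi = log_trans[_NORMAL]

    delta = log_pi + log_emit[0]
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # cand[i, j]: best-to-i then i->j
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + log_emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _calls_from_path(
    path: np.ndarray, positions: np.ndarray, lrr: np.ndarray, pool: str, chrom: str
) -> list[CNVCall]:
    calls: list[CNVCall] = []
    n = path.size
    i = 0
    while i < n:
        state = path[i]
        j = i
        while j + 1 < n and path[j + 1] == state:
            j += 1
        if state != _NORMAL:
            seg = lrr[i : j + 1]
            calls.append(
                CNVCall(
                    pool_id=pool,
                    chrom=chrom,
                    start=int(positions[i]),
                    end=int(positions[j]),
                    status="loss" if state == _LOSS else "gain",
                    n_markers=j - i + 1,
                    mean_lrr=float(np.mean(seg)),
                    sd_lrr=float(np.std(seg)),  # population SD; 0 for 1 marker
                )
            )
        i = j + 1
    return calls


def viterbi_segment(
    markers: pd.DataFrame, pool: str, params: HMMParams | None = None
) -> list[CNVCall]:
    """Segment one pool's LRR into gain/loss calls, chromosome by chromosome.

    ``markers`` must be QC-passed (finite LRR) and sorted by (chrom,
    position).  Raises ``ValueError`` on non-finite LRR.
    """
    params = params or HMMParams()
    calls: list[CNVCall] = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        lrr = sub[f"{pool}.lrr"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lrr)):
            raise ValueError(f"non-finite LRR for pool {pool} on chromosome {chrom}")
        sd = params.emission_sd
        if sd is None:
            sd = max(estimate_noise(markers, pool), 1e-6)
        path = _viterbi_path(lrr, params, sd)
        calls.extend(
            _calls_from_path(path, sub["position"].to_numpy(), lrr, pool, str(chrom))
        )
    return calls


def call_all_pools(
    dataset: PooledDataset,
    params: HMMParams | None = None,
    markers: pd.DataFrame | None = None,
) -> dict[str, list[CNVCall]]:
    """Run :func:`viterbi_segment` for every pool in the manifest.

    ``markers`` defaults to ``dataset.signals`` (pass the QC-retained table
    in the normal pipeline).  Raises ``ValueError`` if the signal table
    carries a pool absent from the manifest.
    """
    params = params or HMMParams()
    if markers is None:
        markers = dataset.signals
    signal_pools = {c.split(".", 1)[0] for c in markers.columns if c.endswith(".lrr")}
    manifest_pools = set(dataset.pools)
    orphans = signal_pools - manifest_pools
    if orphans:
        raise ValueError(f"pools in signal table but not manifest: {sorted(orphans)}")
    return {pool: viterbi_segment(markers, pool, params) for pool in dataset.pools}
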