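# Methods

## Signal model for pooled arrays

A pool of `n` subjects assayed as one sample reports, at each probe, a
noisy estimate of the pool-average intensity. For copy number, the
expected pool Log R ratio is

    LRR = log2(c̄ / 2),   c̄ = ((n − k)·2 + k·c) / n,

where `k` subjects carry copy number `c` and the rest are diploid. An
all-diploid pool sits at 0; one duplication carrier (c = 3) in 25 shifts
the pool by +0.0286, one hemizygous deletion (c = 1) by −0.0291, one
homozygous deletion (c = 0) by −0.0589. These shifts set the scale of the
whole problem: they are an order of magnitude below typical per-probe
noise, so detection relies on run-length evidence across many consecutive
markers and on conservative downstream filtering.

The simulator (`poolcnv.simulate`) draws pool-level Gaussian noise around
that mean. The default noise SD is **0.15**, placing single-carrier events
near the detection edge; the demo study uses 0.05, a middle ground at
which multi-carrier events are reliably recoverable while single carriers
are still marginal. Pooled B allele frequency is modeled as a binomial
allele proportion over the 2·n pooled chromosomes (population allele
frequency per marker ~ Uniform(0.05, 0.95)) plus small truncated Gaussian
jitter; carrier-dosage perturbation of BAF is omitted because the caller
is LRR-only and pooled BAF is nearly uninformative for 1-in-25 carriers.
Inter-marker spacing is exponential with configurable mean (default
2.5 kb). Data pathologies — missing signal cells, GC scores of exactly
zero, and artifact probes whose LRR is offset by +4 or −8 across all pools
— are injected at configurable per-cell/per-marker rates so the QC stage
is exercised, and a configurable fraction of markers is placed on chrX
solely to exercise the sex-chromosome removal rule.

What the simulator does **not** emulate: array normalization chemistry,
GC-content intensity waves, batch effects, distance-dependent noise
correlation, or subject-level genotypes. Passing tests therefore
demonstrate the pipeline's logic and calibration under idealized pooled
noise, not robustness to platform-specific artifacts.

## Marker QC

Three rules, applied in fixed order, each to the survivors of the previous
one: (1) any missing LRR/BAF/GC value in any pool, or a sex-chromosome
location; (2) GC score exactly 0 in more than `max_gc_zero_pools` pools
(default 3); (3) median LRR across **all** pools (cases and controls
jointly) above 1 or below −5. All inequalities are strict — a marker with
median exactly 1 or −5, or zero GC in exactly 3 pools, is retained. The
even-count median is the mean of the two central order statistics. A
marker failing several rules is attributed to the first failing rule, which
makes the QC report's removal counts additive. The "missing" rule counts
any missing field (LRR, BAF or GC): the interpretation is deliberately
inclusive, since a pool-level probe failure corrupts all three.

## Segmentation HMM

Three states (loss, normal, gain) with Gaussian emissions on pool LRR;
default emission means −0.03 / 0 / +0.03 — pool-scale values of order a
single-carrier shift — and a shared emission SD estimated per pool as
MAD × 1.4826 (robust to the CNV markers themselves) unless fixed in
config. Transitions are time-homogeneous and distance-independent: each
state keeps probability `1 − 2q` and switches to each other state with
`q` (default 1e−4); the initial distribution is one transition step out of
the normal state. Decoding is exact Viterbi in log space; `argmax` ties
break toward the lower state index (loss < normal < gain), a convention
that can only matter on measure-zero inputs. Maximal runs of a single
non-normal state become calls; call coordinates are the first and last
marker positions of the run (not midpoints to flanking markers — the
simplest defensible convention). Call mean/SD are computed over the pool's
LRR at the run's markers with population (ddof = 0) normalization so a
one-marker segment has SD 0.

This is a deliberate simplification of individual-level array callers,
which use six copy-number states, joint LRR+BAF emissions and
distance-dependent transitions. At pool level the extra machinery buys
nothing: downstream logic needs only gain/normal/loss, pooled BAF carries
almost no carrier information, and simulated spacing is uniform. The
trade-offs are documented here rather than hidden behind the interface.

## Region operations

Coordinates are 1-based inclusive in memory (length = end − start + 1;
overlap iff max(starts) ≤ min(ends)); BED-like files on disk are 0-based
half-open, converted at I/O. The published worked-example coordinates
reproduce their printed kb lengths exactly under the inclusive convention,
which is why it was chosen.

Filter order: minimum-marker filter (≥ 20), then gain-quality filters
(mean LRR ≥ 0.02 and LRR SD ≤ 0.2, gains only — at/beyond the bound is
removed strictly, values exactly at 0.02/0.2 survive), then gap merge,
then cross-pool union. Merged calls are not re-subjected to the earlier
filters. The two pointwise filters commute; their order is narrative, not
semantic.

**Gap merge.** Adjacent same-status calls A, B of one pool/chromosome with
gap `g = start(B) − end(A) − 1` merge when `g/(len(A)+len(B)) < 0.2`. The
sweep is run to a **fixed point**: merging B with C lengthens the merged
call, which can qualify the A-side gap on a later pass, and a fixed point
is the only way the operation is idempotent (a property the test suite
enforces). Merged statistics are recovered exactly from the parts'
sufficient statistics; gap markers contribute nothing, so total marker
count is conserved. Different-status neighbors never merge, and a
different-status call between two same-status calls blocks their merge.

**Cross-pool union.** Single-linkage clustering of calls from all pools
with ≥ 1 bp overlap, per chromosome; each cluster spans min start to max
end. Output regions are disjoint and invariant to pool input order
(verified against a brute-force transitive-closure oracle). Per-group
"unique region" counts are computed by running the union within each group
separately; the cross-group union is what classification consumes. A
region records, per pool, the *set* of statuses contributed (normally a
singleton; a pool can in principle contribute both a gain and a loss call
to one cluster, and collapsing that to one label would lose the
status-conflict signal).

## Classification

Four rules against a reference CNV map (any-overlap, ≥ 1 bp, defines "in
the map"; the map is an input BED file — no population catalogue is
bundled, and tests use synthetic maps):

- different status: both groups present, status sets disjoint (checked
  first — it is the only rule about status rather than counts);
- important in cases: case-only and not in the map;
- important in controls: control-only and in the map;
- enriched: both groups present and |case pools − control pools| ≥ 3
  (threshold configurable; the source criteria can be read as either
  "> 3" or "difference of three", and "≥ 3" matches the worked category
  counts — both readings are available via `freq_diff_threshold`).

Rules 1–3 are mutually exclusive by their count conditions, so after the
status-conflict check the order is immaterial; every region gets exactly
one label (enforced by an exhaustive truth-table test over count grids
0..8 × 0..8).

## Association testing

**Exact rank-sum.** With 8 + 8 pools, the Wilcoxon two-sided p-value is
computed by full enumeration of all C(16,8) = 12 870 group assignments of
the pooled mid-ranks; the two-sided p is `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`.
The smallest attainable p is 2/12 870 ≈ 1.55e−4; identical groups give
p = 1. Mid-ranks make the enumeration the exact conditional null given the
tie pattern, which matters because burden counts are small integers with
heavy ties.

**Burden.** Per stratum (gain/loss/both × length ≥ 100/500 kb): per-pool
post-filter call counts, group means, within-group-union unique counts,
and the exact rank-sum p — reported as NA when no pool has any call in the
stratum (the test is undefined on all-zero data).

**Region signal test.** Per pool, the median LRR over QC-retained markers
inside the region; Welch's t (the safer default when group variances may
differ; it coincides with Student's t to < 1e−6 when sample SDs are equal)
and the exact rank-sum on the 8-vs-8 medians. When both groups are
constant the t statistic is undefined and reported as NA rather than 0 or
1. No multiple-testing correction is applied to per-region p-values; the
pipeline reports raw p with configurable screening (0.2) and significance
(0.05) thresholds, mirroring discovery-stage practice for small designs.

**Power.** Two-sided two-sample t-test power via the noncentral t
distribution (df = 2n − 2, ncp = δ/(σ·√(2/n))); at δ = 0 the formula
returns exactly α. Cross-checked against a 100 000-replicate Monte-Carlo
oracle to within 0.01 absolute.

## Determinism and problem sizes

Every random draw flows from a single integer seed through
`numpy.random.default_rng`; equal seeds give byte-identical dataset files
and report bundles (config hash in the run log covers the analysis
parameters, not the output location). The bundled test suite and the
acceptance script run on deliberately modest problem sizes — thousands of
markers, 500 calibration windows, 100k power replicates, oracle instances
of ≤ 8 markers / ≤ 20 calls — chosen so the full validation cycle completes
in well under a minute on one core while still pinning every algorithmic
property of interest.

## Known limitations

- The HMM is a stand-in: no BAF, three states, distance-independent
  transitions. Absolute sensitivity/specificity numbers on real
  platform data would differ.
- Single-carrier events at realistic pool noise (SD ≳ 0.05) are by design
  at or below the detection edge; the pipeline does not pretend otherwise.
- The noise level of real pooled arrays is instrument- and
  protocol-specific; `lrr_noise_sd` is exposed in config and the default
  (0.15) is a deliberately conservative stand-in, not a measurement.
- Covariate adjustment is impossible under pooling (pools fix the design);
  the association layer offers none.
- Gene-desert regions are reported like any other; the annotation layer
  flags, it does not filter.
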