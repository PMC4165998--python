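# Methods

## Model

An SV genotype/allele-fraction problem is cast as maximum-likelihood
estimation over independent Poisson evidence channels. For a candidate SV
with allele fraction `p ∈ [0, 1]`, the data `D` are the channel counts in
the encompassing window, and every channel rate is affine in `p`:

| channel | rate(p) | applies to |
|---|---|---|
| depth bin `i` | `a_i (1 − p)` (DEL), `a_i (1 + p)` (DUP) | unbalanced SVs |
| discordant pairs per junction | `v_d · c · (t − 2r) · p` | all |
| soft-clips per junction | `v_s · c · 2r · p` | all |

with `a_i = c(θ_i)·|w_i|`, `c(θ)` the GC-stratified pair rate per bp, `r`
the read length, `t` the insert-size median. `t − 2r` is the *span* (physical)
coverage contribution of one pair — the stretch of an insert not covered by
its reads, which is what a junction-spanning discordant pair samples — and
`2r` the sequenced bases, which is what a clip-producing read samples.
Balanced SVs (INV, reciprocal TRA) contribute no depth channel and two
independently counted junctions. The duplication depth factor `1 + p`
models a single extra tandem copy; multi-copy gains are out of scope.

The log-likelihood is the sum of Poisson log-pmfs over channels (and over
libraries, which multiply). Since `d/dp log L` is a sum of terms
`σ_f (K_f/u_f(p) − S_f)` over at most two rate families
`u ∈ {1−p, 1+p, p}`, its numerator is a quadratic in `p`; `mle_vaf` solves
it exactly and compares the admissible roots with the boundaries `{0, 1}`,
breaking ties toward the smaller `p`. The implementation is validated
against an exhaustive 1e-4 grid search on 1000 random channel
configurations (agreement ≤ 1e-3; the equation bodies were not available
in the source text, so the affine forms are additionally validated by the
printed simulation behavior).

### Noise floor

Raw rates make `L(D | p=0)` exactly zero whenever a single stray
discordant or clipped read exists, which degenerates the confidence score.
Each channel rate is therefore floored at `ε · max_{p∈[0,1]} rate(p)` with
`ε = 0.01` (plus an absolute floor of 1e-6 expected counts) before log-pmf
evaluation — a crude mismapping-noise model that keeps all likelihoods
finite. `ε` is exposed (`noise_floor_eps`). The MLE accounts for the floor
by solving the stationary condition piecewise between floor-crossing
points of `p`.

### Genotyping and confidence

Genotypes AA/AB/BB are the discrete points `p = 0, ½, 1`. The posterior is
Bayes over the three likelihoods with either a uniform prior (default —
appropriate when `p` is continuous and the genotype is only a summary) or
Hardy–Weinberg weights `((1−q)², 2q(1−q), q²)`; `q` defaults to 0.01 and
is flag-exposed, since no canonical population SV frequency exists. The
error probability is the posterior mass on AA, floored at 1e-10, and
`VarScore = −10·log₁₀(error_prob)` capped at 99 (Phred convention; the
scale choice is ours and documented as such). All posterior arithmetic is
in log space with log-sum-exp.

## Calibration

Library parameters are measured from `N` randomly sampled regions of the
BAM (defaults `N = 10`, 10 Mb each; both flag-exposed, and scaled down in
tests to match the synthetic genome sizes). Centromere/telomere exclusion
intervals may be supplied as BED; none are built in, since no coordinates
were prescribed. Choices worth noting:

* **Insert size** is the outer distance (SAM TLEN convention) of flagged
  proper pairs; the spread is `1.4826·MAD`, robust to chimeric outliers.
* **Pair rate** `c` counts each proper pair once at the leftmost aligned
  base of its left mate. The *same* convention assigns pairs to depth bins
  at estimation time, so the calibrated rates cancel correctly in the
  likelihood.
* **GC table**: per-bin GC percent (integer 0–100) comes from the
  reference when given, else from aligned read bases (an approximation
  that underestimates extreme strata). Strata supported by fewer than 50
  bins fall back to the global mean rate.
* **Offsets** `v_d, v_s` default to 0.8 and 0.7 — typical shortfalls of
  observed junction counts against the idealized rates in short-insert WGS
  — and can be trained as observed/expected count ratios over a truth set,
  clamped to [0, 1].

## Evidence extraction

A read record is EXCLUDED (duplicates, secondary/supplementary, QC-fail,
unmapped mate), else SOFTCLIP if it carries a clip ≥ 5 bp within ±5 bp of
a predicted breakpoint (the clip is the most specific signal and wins over
pair-level classes; a read clipped at both junctions counts once, at the
nearer one), else DISCORDANT if the pair's anomaly is geometrically
consistent with the candidate SV, else NORMAL if FR-oriented with insert
within `t ± k·spread` (`k = 3`). The consistency gates — enlarged insert
spanning both breakpoints (DEL), everted RF pair inside the interval
(DUP), same-strand pair near the breakpoints (INV), inter-contig mates
near both loci (TRA) — exist so that counts are attributable to *this* SV
rather than to any anomaly in the window; unexplained anomalies are
excluded rather than counted. Junction windows have half-width
`t + k·spread` (flag-exposed); depth bins tile `[pos1, pos2)` at 100 bp
with the last bin short, and bins with MQ0 fraction > 0.5 are dropped
before the likelihood.

## Simulation design

The accuracy studies are **count-level**: trial counts are drawn directly
from the model's Poisson channels (`c = coverage/(2r)`), estimates are
recomputed by the closed-form MLE, and accuracy is the fraction of trials
with `|p̂ − p| ≤ 0.10·p` — a *relative* band, the reading consistent with
the deep-coverage SNV behavior (an absolute ±0.1 band would saturate at
500×). At `p = 0` the band degenerates to exact recovery of zero. The SNV
comparator is `k/n` with `k ~ Binomial(round(coverage), p)`, no shrinkage.

The clone-mixture study emulates a 5-clone tumor whose 10 heterozygous
single-copy 1.5 Mb SVs (deletions and one-copy tandem duplications) have
true VAFs `{0.05, 0.075, …, 0.25, 0.3}·(1 − μ)` for contamination `μ`,
at a fixed 50× total coverage. Clone mass fractions are
`(0.05, 0.10, 0.15, 0.30, 0.40)` with fixed per-SV carrier sets chosen to
hit those VAFs; the carrier sets are a mock lineage, not a strict tree
(ten distinct VAFs cannot all be clades of a 5-leaf tree). Each SV×μ cell
is simulated once, mirroring a single synthetic dataset, and errors are
summarized as mean and max `|p̂ − p|`. This is a deliberate, scaled-down
count-level analog of a full read-simulation/alignment protocol; it tests
the estimator, not the aligner.

A known, analytically verifiable artifact of the relative band on
count-lattice estimators: accuracy at a grid point is the probability of a
discrete count landing in a narrow interval, which is *not* monotone in
coverage at low rates (e.g. the exact SNV accuracy at `p = 0.2` is 0.410
at 5× but 0.179 at 30×, because `k = 1` of 5 reads reproduces 0.2
exactly). Depth-driven kinds (1 kb and 1 Mb deletions) are monotone
everywhere we checked. The property test asserting universal coverage
monotonicity therefore fails at these resonance cells by design of the
band, not by an estimator defect.

### Read-level fixtures

`generate_fixture_bam` writes a sorted, indexed BAM over a random synthetic
genome with planted SVs: proper pairs genome-wide at rate `c` (thinned by
`p` inside deletions, boosted by `p` inside duplications, and optionally
thinned by a user GC-bias function evaluated on the 100 bp at the pair
start — the bin-assignment convention); discordant pairs with type-correct
junction geometry at rate `v_d·c·(t−2r)·p` per junction; and
breakpoint-clipped reads at `v_s·c·2r·p`. The planted `v_d, v_s` emulate
aligner losses so offset training is testable. The generator produces no
sequencing errors, no quality variation, no repeats and no mappability
structure; passing end-to-end tests therefore demonstrate correctness of
counting and estimation on clean alignments, not robustness to real-data
artifacts (MQ0 filtering, for instance, is exercised only synthetically).

## Defaults and degenerate inputs

bin width 100 bp; `k = 3`; MQ0 threshold 0.5; min clip 5 bp; clip slop
5 bp; junction half-width `t + 3·spread`; `ε = 0.01`; VarScore cap 99;
HWE `q = 0.01`. If `t ≤ 2r` the span coverage is non-positive and the
discordant-pair channel is dropped with a warning; a variant with no
informative channel raises "unidentifiable"; an SV file with no records
produces an empty result table; per-SV failures become flagged rows rather
than aborting a run. Tumor/normal pairs are estimated independently per
sample; the only built-in joint screen is the LOH helper (normal VAF
0.45–0.55, tumor ≤ 0.05 or ≥ 0.95). Joint multi-SV clonal clustering,
purity/ploidy deconvolution, SV discovery, breakpoint refinement and VCF
ingestion are explicitly out of scope.
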