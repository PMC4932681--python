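# Methods

This note documents the models and procedures implemented in `dsresist`,
the parameter choices that matter, what the synthetic benchmarks do and do
not demonstrate, and the numerical decisions a maintainer would want
written down.

## Dose-response scoring

### Normalization

Each 384-well plate carries ≥ 16 vehicle (negative) and ≥ 8 full-kill
(positive) control wells. Percent inhibition is
`100 (neg_mean − signal)/(neg_mean − pos_mean)` per plate. A plate with
fewer than two of either control, or with `neg_mean ≤ pos_mean` (an
inverted or failed plate), is a hard error rather than a silent skip,
since every downstream number depends on this anchoring. Control means and
CVs are reported per plate as the only well-level QC.

### 4PL fit

The four-parameter logistic in x = log10 molar is fitted by bounded
trust-region least squares. Bounds: bottom ∈ [−20, 100] (negative values
absorb growth stimulation), top ∈ [0, 100], midpoint within the tested
window ± 2 decades, slope ∈ (0, 10]. Five starts place the midpoint at
each tested log-dose; the lowest-SSE solution wins, ties resolved toward
the smallest slope (the least step-like curve). Responses are *not*
clamped or re-normalized before fitting; the fitted curve is used as-is.

A solver run that exhausts its iteration budget but holds a finite,
in-bounds solution is treated as converged: this arises for near-flat
noisy profiles where the optimizer zigzags at the slope bound without
moving the SSE, and discarding those fits would zero out genuinely weak
responses. The non-converged flag is reserved for runs with no usable
solution at all; such curves score DSS = 0 with a warning.

An all-identical response vector short-circuits to a flat curve
(top = bottom), which is exact and avoids a degenerate optimization.

### DSS

DSS integrates the fitted curve above an activity threshold `Amin` over
the tested window and normalizes by the maximal achievable area
(`(100 − Amin)(x2 − x1)`), scaled ×100 — the area-fraction variant fully
determined by the fitted parameters. The integral is closed-form via the
4PL antiderivative `(t−b)/(s ln 10) · ln(1 + 10^{s(x−m)})` with the
threshold crossing `x_A = m − (1/s) log10((t−b)/(Amin−b) − 1)` handled
analytically; `ln(1+10^u)` is computed with `logaddexp` to avoid overflow
at large slopes. `Amin` defaults to 10% inhibition: responses below it are
considered assay noise and never contribute. Top asymptotes are capped at
100% inside the integration only. The closed form is validated against
kink-aware adaptive quadrature to 1e-6 relative across random parameter
draws.

dDSS = DSS(resistant) − DSS(parental) per pair; a drug missing on either
side yields a missing value excluded from downstream statistics.

## Differential statistics

Hits use a strict cutoff: dDSS > 5 (sensitizing) or < −5 (co-resistant);
exactly ±5 is not a hit. Drugs whose |dDSS| stays below the cutoff in
every pair are listed as omitted for display purposes.

Clustering is complete linkage. Drugs: 1 − Spearman correlation of their
per-pair profiles (average ranks on ties); a constant profile has no rank
correlation and is pushed to the maximum distance 2.0, with a log entry.
Samples: Euclidean distance. Leaf order is scipy's deterministic ordering
for the given input order. Spearman makes drug clustering invariant to
per-drug monotone transforms, which is tested.

The rank product per direction is the geometric mean of a drug's per-pair
ranks (descending dDSS for sensitizing, ascending for co-resistant;
average ranks on ties). p-values come from B within-pair independent
shuffles of the observed rank columns: `p = (1 + #{RP_perm ≤ RP_obs})/(B+1)`,
counted at the drug's own index. B defaults to 10,000. q-values are
Benjamini–Hochberg; the original RankProd "expected false positives"
estimator was not implemented — BH on permutation p-values is standard
and sufficient at this scale. The permutation scheme is exact-level; its
null type-I error and p-value uniformity are verified by simulation, and
small cases against exhaustive rank enumeration. We rank per-pair dDSS (a
one-sample rank-product design) rather than comparing raw DSS between
groups; with isogenic pairs the paired difference is the quantity of
interest, and the alternative would discard the pairing.

## Copy number

*Region merging.* Capture regions with gaps strictly < 76 bp are merged
(idempotent).

*Metrics.* RPKM = count/((len/1000)(total/10⁶)); the mapped-read total
defaults to the on-target sum of the supplied counts. "Coverage" is not
reconstructable from counts alone without a read length, so it is defined
as count × read_length/region_length with read_length from configuration
(default 100 bp). Both members of a pair must reach 25× for a region's
ratio to be kept — a ratio is unreliable if either side is.

*log2 track.* log2((RPKM_s + ε)/(RPKM_r + ε)) with ε = 0.01 RPKM guarding
empty regions; optional median-centering, off by default. Note that
library-size normalization makes large aberrations shift the genome-wide
baseline slightly (a sample that lost a big segment has its remaining
RPKM inflated); median-centering exists for samples where this matters.

*CBS.* Per chromosome, the arc (i, j] maximizing the two-sample
t-statistic against its complement is a split candidate; the candidate is
accepted when its permutation p (B = 1000 shuffles of region order,
max-statistic null) is < α = 0.01, then the pieces recurse. Minimum
segment width 2 regions; no pruning/undo heuristic — at desk scale the
exact-level permutation test needs no correction, and the measured null
false-split rate is ≈ α (0.95% over 4000 simulated null chromosomes).
Permutations stop early once significance is impossible; this never
changes a decision, only saves time. Ties and cancellation dust on
constant tracks are guarded by a relative tolerance so an exactly
constant chromosome always yields one segment. Arithmetic segment means
reconstruct the track mean exactly.

*Gene calls.* A gene overlapping (≥ 1 bp, BED half-open coordinates)
multiple segments takes the lowest segment value if any overlapped
segment is ≤ −0.6, the highest if any is ≥ +0.5, otherwise the median —
with both thresholds inclusive. A gene overlapping both an extreme-low
and an extreme-high segment is contradictory under that rule; we assign
the value of larger absolute magnitude (tie → the deletion) and flag the
gene in the output. Categories at inclusive log2 limits: ≤ −1.2
homozygous deletion, ≤ −0.4 heterozygous deletion, ≥ +1.3 amplification,
≥ +0.5 gain, else neutral. No GC/mappability correction and no ploidy or
sex-chromosome adjustment are applied.

## Somatic variants

The somatic statistic is the one-tailed Fisher's exact p-value for
alt-read enrichment in the resistant sample, computed as the exact
hypergeometric upper tail of the paired 2×2 count table. Being discrete,
it is conservative near the null — its p-values are stochastically larger
than uniform, which the tests check rather than exact uniformity.

Filters run sequentially with per-step tallies: normal depth ≥ 8, tumor
depth ≥ 6, tumor VAF ≥ 0.05 (inclusive — the boundary convention at 0.05
is ours; the high-confidence VAF bound is strict > 0.30), strand bias
(removed when > 90% of tumor alt reads sit on one strand *and* alt reads
≥ 4 — below four reads strand imbalance is uninformative), population-
variant list membership, then effect class: known-silent classes are
removed, protein-altering classes kept, and unknown labels kept with a
log entry (dropping unrecognized annotations silently would be worse than
keeping them). Depth is ref + alt, the only definition available from
count tables. An optional user blacklist substitutes for visually
validated false-positive lists. High confidence = p < 0.05 and VAF > 0.30.

## Drug-target integration

Per (drug, target): median of each assay type's µM values; the IC50
median is divided by a fixed factor 2 before combining (IC50s run
systematically higher than Ki/Kd; the learned per-type offsets of the
full KIBA scheme are not reproducible from a flat value table, and the
factor is configurable); the integrated score is the mean of available
adjusted per-type medians. The specificity thresholds (0.1, 50×, 3) are
interpreted on this integrated µM-like scale. Specific targets score
strictly below the drug's threshold.

Effector tables require ≥ 3 hit drugs per pair × direction; below that no
table is built (logged), mirroring the practice of not drawing networks
from one or two drugs. Hit drugs lacking target data remain in the table
with an empty target set so the drug list stays faithful. Target genes
are annotated with their copy-number category and a mutated flag when a
high-confidence protein-altering mutation hits the gene. Pathway-tool
network expansion is replaced by a plain annotated bipartite drug → target
export (nodes/edges files): proprietary interaction knowledge bases are
not reproducible, so only the directly supported edges are emitted.

## Synthetic data: what it emulates, and what it does not

The screen generator lays out 384-well plates (72 drugs × 5 doses + 16
negative + 8 positive controls), doses spanning exactly 10⁴-fold, signals
from the true 4PL inhibition via `signal = neg − inh/100 (neg − pos)` with
multiplicative Gaussian noise (CV default 5%, a typical luminescence
assay figure) applied to drug and control wells alike — making
normalization exactly invertible at zero noise. The default library truth
makes roughly half the drugs active (top 40–100%), the rest near-inactive,
IC50s inside the tested window, Hill slopes 0.5–2.

The exome generator draws parental counts Poisson with mean
coverage × len/read_length (default 100× — comfortably above the 25×
filter so the CNV benchmarks probe segmentation, not dropout) and
resistant counts Poisson with the mean scaled by 2^(true log2) of
embedded piecewise-constant blocks. Overdispersion beyond Poisson,
GC/mappability bias, and read-level error models are deliberately absent:
the generator tests the arithmetic and the segmentation statistics, not
alignment artifacts. Somatic variants carry binomial alt counts at their
true VAF in the resistant sample only; germline variants sit at VAF 0.5
in both samples and populate the population-list stand-in.

The bioactivity generator designates true specific targets per drug and
emits measurement rows whose per-type medians integrate exactly back to
the intended score, so specific-target recovery has a sharp truth.

Passing these benchmarks therefore shows the implementation is correct
under its stated models; it does not show robustness to capture bias,
overdispersed counts, mislabeled controls, or bioactivity curation noise
in real data.

### The IC50-recovery benchmark

The recovery benchmark (≥ 90% of log10 IC50 within ±0.2 at 5% CV) is run
on `potency_recovery_truth`: tops 70–100%, slopes 0.8–2, IC50 at least a
decade from the window edges. This is a deliberate restriction to curves
whose IC50 a five-point design can identify at all: isolated checks show
~99% recovery for full-range unit-slope curves but ~30% for weak shallow
ones (top 40%, slope 0.6) — an information limit of the design, not a
fitter property. Weak responses are what DSS is for; quoting an IC50 for
them would be meaningless, so they are excluded from this benchmark while
remaining part of every other test and of the default library truth.

## Problem sizes

Simulation-based checks use: 1000 random curves for the DSS closed form;
200 drugs for IC50 recovery; 500 drugs × 4 pairs with 10,000 permutations
for the rank-product null; 200 null chromosomes of 100 regions (1000
permutations each) for CBS specificity plus one 200-region track with an
embedded 60-region shift for breakpoint recovery; 1000 random layouts for
the gene-call oracle; and a 24-drug / 140-region / 22-variant end-to-end
study. These sizes give each check stable statistics while keeping the
full validation run in the order of a minute.

## Known limitations

- CBS here has no undo/pruning step and no hybrid tail approximation; on
  very long chromosomes the O(n²) arc scan per permutation grows costly.
- The rank product assumes within-pair exchangeability of drugs under the
  null; strong plate effects violating this are not modeled.
- KIBA integration with a fixed IC50 factor is an approximation of the
  published learned weighting.
- Variant filtering operates on supplied allele counts; it cannot rescue
  alignment- or pileup-level artifacts, and indels are taken as annotated
  without left-normalization.
- The synthetic study conditions are small (desk-scale); rates measured
  on them carry the Monte-Carlo error of their stated problem sizes.
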