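# Methods

## Variance-stabilizing transform

RNA-seq abundances are overdispersed and span orders of magnitude across
genes. Before GP regression every abundance x of gene i is mapped through

    f(x) = log2((x + α) / (mᵢ + β)),   α = 1, β = 1000,

where mᵢ is the gene's maximum abundance over all samples (both
conditions, all timepoints). The transform is strictly increasing, total
on x ≥ 0, depends on the gene only through mᵢ, and its inverse
x = 2ʸ(mᵢ + β) − α is applied to GP medians and interval bounds to report
trajectories on the original TPM scale. The inverse is defined for any
real y (yielding x ≥ −α); interval lower bounds may correspond to
negative abundances and are reported as-is rather than clipped, so the
ordering low ≤ median ≤ high survives the monotone back-transform
exactly.

## GP model and the LR statistic

Each transformed series is modelled as a zero-mean Gaussian process with
Matérn-5/2 covariance

    k(r) = σ_f² (1 + √5 r/τ + 5r²/3τ²) exp(−√5 r/τ),  r = |t − t′|,

plus i.i.d. Gaussian observation noise σ_n². Because the raw VST values
sit several log2 units below zero, the empirical mean of the series being
fit is subtracted before regression and added back to the posterior mean;
the pooled fit uses the pooled mean, so a genuine condition offset is
retained as signal in the separate-versus-pooled comparison while a
shared offset is not charged to σ_f.

Hyperparameters are optimized in log space as a MAP under independent
normal priors

    log σ_f ~ N(0, 1²),  log τ ~ N(log 2.5, 0.5²),  log σ_n ~ N(−1.5, 1²)

(units: transformed-abundance for σ_f, σ_n; hours for τ). The defaults
keep the timescale comparable to developmental-stage spacing and the
noise below the signal; all three are configurable. Optimization runs
L-BFGS-B with analytic gradients from the prior mean plus four prior
draws (fixed seed), then polishes the best endpoint with Nelder–Mead; a
relative jitter of 1e-8·σ_f² is added to the diagonal if the Cholesky
factorization fails. The stored log-likelihood excludes the prior terms
(switchable to the penalized form), so

    LR = L_U + L_M − L_UM

compares marginal likelihoods of the two-trajectory model (separate UIC
and MO fits) against a single trajectory through the pooled points. The
pooled fit deliberately allows duplicate time values. LR is symmetric
under exchanging condition labels. Direction is "increased" when the MO
GP median exceeds the UIC median on average over the prediction grid,
with exact ties classed as "decreased".

No closed-form null distribution is assumed: `null_lr_threshold`
simulates null genes (identical trajectory law in both conditions,
independent noise at the analysis noise level) and takes an upper
quantile of their LR values (default: the 99.5th percentile). On this
package's null simulations LR is frequently negative — pooling 2n points
often explains the data better per likelihood unit than two n-point fits
with separately penalized hyperparameters — which is expected and
harmless, since calls are made against the empirical quantile.

## Trajectory clustering

For each called gene the UIC and MO GP medians are divided by the shared
maximum of the two and concatenated, so every feature vector lies in
[0, 1] with max exactly 1 and scale information removed. Increased and
decreased genes are clustered separately by Lloyd k-means with k-means++
seeding from a fixed RNG (seed 1618033). The Lloyd loop asserts its
objective is non-increasing each iteration and re-seeds any empty cluster
with the farthest point. k is chosen by the maximal mean silhouette
(Euclidean) over k = 2..10; across multiple runs (two library types ×
two directions) the pipeline reports the mode of the per-run selections.
Cluster names U1..Uk / D1..Dk are assigned by ascending divergence-onset
time of the cluster mean — the first grid index where |MO − UIC| of the
mean trajectory reaches half its maximum — so U1 always denotes the
earliest-diverging cluster.

## Sequence enrichment

Seed matching happens entirely in transcript-sense DNA space: seeds are
the reverse complement of the miRNA subsequence with U→T (canonical
7-mer = nt 2–8, offset 6-mer = nt 3–8, extended 8-mer = nt 2–9), and UTRs
are scanned on one strand only. Matches are counted at every start
position (overlaps included); gene-level counts default to the maximum
over isoform UTRs (configurable to the sum), avoiding inflation for genes
with many annotated isoforms. Enrichment of "≥ N copies" versus cluster
membership is a right-tail Fisher exact test per (pattern, cluster, N);
element motifs (EDEN as its exact 39-nt literal, ARE = ATTA,
YTHDF2 = RRACH in IUPAC code) are tested at N = 1 only. Each seed's
mismatch class is its minimal Hamming distance over all offsets within
the extended miR427 seed AAAGCACTTTC.

PWM scores are per-position log2 likelihood ratios against a supplied
genomic background 4-vector, with count matrices converted to
probabilities via a background-distributed pseudocount (default 0.8,
common JASPAR practice). A gene's score is the max over all windows of
all its 500-bp promoters on both strands (transcription-factor sites are
orientation-agnostic; forward-only scanning is available). The per-motif
threshold is the observed score > 5 minimizing the Fisher right-tail p of
above-threshold × in-any-cluster, ties resolved toward the lower
threshold; cluster-level enrichment is then reported at that fixed
threshold. Log base 2 is a configuration choice, not a claim about any
particular published threshold scale.

## Locus reads and fragment inference

A read with N reported alignments contributes 1/N to the coverage pile at
every position of every alignment, conserving exactly one unit of span
per read; mass conservation is asserted on every pile build. Retention
for the repetitive locus is strict by default — all of a read's
alignments must fall inside the interval — because counting reads that
also map elsewhere would inflate the locus signal; a permissive
"any alignment inside" policy is available. Coordinates are 0-based
half-open; interval length is end − start.

Short insert fragments are recovered from a read pair by scanning
candidate lengths f = 1..L−1 (smallest first) and accepting the first f
where R1[1..f] is the reverse complement of R2[1..f] and the remainder of
R1 matches the adapter prefix over the available overlap, both within a
configurable mismatch budget (default 0). Fragments shorter than the
mature query sequence count as instances when they are substrings of the
query; longer fragments count when they contain it.

## Synthetic data: what it does and does not emulate

The generator reproduces the design features the analysis relies on: a
shared, evenly spaced time grid (default 20 points at 0.5 h, emulating
30-min sampling), two conditions with identical trajectory laws for null
genes, planted trajectory classes (maternal decay with clearance blocked
or limited from a divergence onset; zygotic sigmoid activation scaled up
or down; constants), two library types with independent noise, UTRs with
exact rejection-sampled seed copy numbers, promoters with planted PWM
consensus sites, multi-mapping locus alignments, and adapter
read-through read pairs. Expression noise is multiplicative lognormal
with unit mean and configurable CV — a stand-in, since the emulated
experiments publish no count-noise model; it is simple, strictly
positive, and monotone under the log-family VST. Not emulated: alignment
and base-call error, positional coverage bias, library-size and spike-in
normalization artifacts, correlated (batch) noise, and realistic UTR base
composition. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not robustness to
real-data pathologies such as overdispersion beyond the lognormal or
misalignment.

## Problem sizes and numerical choices

Default analysis sizes were chosen so a complete run is comfortable on a
single CPU: the bundled pipeline config simulates 60 genes with a
100-gene null calibration, and the headline-reproduction script uses four
runs of 240 genes (three planted shape clusters of 80). LR calibration
experiments use 1,000 null genes. Degenerate inputs are rejected loudly
rather than coerced: duplicate times in a single-condition fit, all-zero
trajectories in normalization, zero-total PWM columns without
pseudocount, empty alignment sets, and empty patterns all raise.
Tie-breaks are deterministic throughout (silhouette ties prefer smaller
k; threshold ties prefer the lower threshold; direction ties class as
decreased).

## Known limitations

- MAP hyperparameters only; no integration over the hyperposterior, so
  LR inherits MAP optimism for both models symmetrically.
- The dinucleotide abundance correction is accepted as a user-supplied
  per-gene factor table (identity by default); the package does not
  derive one.
- The expressed-gene filter evaluates runs within a single condition's
  series by default; an interleaved "pooled" mode is provided because the
  sample-sequence convention is ambiguous in the emulated design.
- EDEN is matched as an exact literal; degenerate EDEN variants must be
  supplied by the user as IUPAC patterns.
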