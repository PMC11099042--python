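# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data generator does
and does not emulate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention); 1-based inputs must
be converted at the boundary. Chromosome names are exact strings (no "chr"
aliasing). Strand is ignored for all peak/anchor overlap operations —
accessibility and loops are unstranded — and consulted only for gene TSS
definitions. Book-ended intervals merge at gap 0, matching the common
merge-tool default and simplifying consensus construction. Contact matrices
travel as coordinate-triplet text with a `#chrom/#resolution/#n_bins`
header; loop lists as BEDPE with count columns named `<condition>_rep<k>`
plus an `fdr` column.

## Accessibility dynamics

Consensus loci are the gap-0 merged union of all time points' peaks, with
the open bit at time t set by ≥ 1 bp overlap with any peak of set t. This is
the simplest reproducible unification; it is isolated behind
`build_consensus` so alternatives (e.g. reciprocal-overlap matching) can be
swapped without touching classification.

Classification is a strict archetype match (PO = all-open, CO_k / OC_k =
single monotone switch at k ∈ [1, T−1]); anything else — all-closed or
flickering — is EXCLUDED rather than smoothed. Smoothing would silently
manufacture classes; the taxonomy admits only monotone patterns. The
classifier is verified against an exhaustive lookup over all 2^T open-state
patterns.

Region definitions: Region 1 = OC of the forward (serum→ground-state)
direction, Region 2 = CO forward, Region 3 = OC reverse, Region 4 = CO
reverse. Sharing statistics count region-A peaks touching ≥ 1 region-B peak
(≥ 1 bp); reported percentages are rounded half-up to one decimal, with the
raw value retained. Gene switch timing uses the earliest switch index among
a gene's region peaks (configurable to latest/modal); the earliest-switch
rule reflects that regulatory turnover concentrates in the initial stage of
the transition.

## TF binding and motifs

Condition specificity is binary non-overlap between peak sets. A
signal-level differential caller needs read pileups, which are out of scope
here; the partition is exact by construction (|a_specific| + |shared| = |a|).

Promoters default to TSS ± 2 kb (`promoter_window`); no standard single
definition exists, so the window is config-exposed. Annotation precedence is
promoter > enhancer > intergenic. Enhancers are consumed as a caller-supplied
BED (typically derived upstream from histone marks); the package does not
call enhancers. Peak→gene assignment: a promoter-overlapping peak maps to
that gene (nearest TSS among overlapped promoters); otherwise the nearest
TSS within `max_dist` (default 100 kb); equidistant ties break to the
lexicographically smaller gene id for determinism.

PWM scanning computes log2 odds against a background (uniform 0.25 unless
supplied) at every offset on both strands; a hit requires score ≥
`frac_of_max` × the maximum achievable score (default 0.8, a common
known-motif scanning operating point). Windows containing N are skipped.
Enrichment is the upper-tail hypergeometric probability of the observed
count of hit-containing target sequences, with Benjamini–Hochberg q-values
reported alongside raw p when several motifs are tested. Gene-set overlap
uses the same tail probability over a user-stated universe.

## Expression dynamics

Specific genes: q < `q_max` (default 0.05) and |log2FC| > log2(`fc_min`)
(default fold-change 2, the specificity threshold; the looser 1.5 sometimes
used for generic DE lists is available by configuration). DE estimation
itself is consumed, not implemented — count-model fitting belongs to
dedicated DE packages.

Clustering operates on log2(x+1) profiles over the fixed condition order
(WT d0/d3/d6, KO d0/d3/d6), centered per gene and scaled by
max(sd, 0.5 log2 units). The variance floor is deliberate: a pure per-gene
z-score maps flat ("unchanged") genes onto amplified noise directions and
scatters them across clusters, whereas flooring keeps them near the origin
where they form their own tight cluster. k-means (k=5, ≥ 10 restarts, fixed
seed) partitions the scaled profiles; cluster→label assignment minimizes
total Euclidean distance between centroids and the five canonical patterns
(Hungarian algorithm), making labels stable across seeds and row orders. The
clusterer is pluggable in principle — the semantic relabeling is what makes
outputs comparable across methods.

## 3D genome

**KR balancing.** The Newton/inner-CG iteration solves x ∘ (Ax) = 1 on the
unmasked submatrix after pre-scaling A to mean row sum 1 (the iteration's
cone safeguards assume biases of order one); biases are rescaled back
afterwards. Non-convergence falls back to damped iterative proportional
scaling (x ← sqrt(x / Ax)), reported in the result info. Bins with zero
marginal are masked by default and stay zero in the output.

**Compartments.** Expected counts per diagonal (mean over unmasked pairs) →
O/E → Pearson correlation matrix → leading eigenvector by power iteration
(tol 1e−8, deterministic start). The eigenvector's global sign is arbitrary,
so orientation requires a caller-supplied per-bin activity track (gene
density or accessibility coverage); the package does not guess from genome
annotation. Default resolution 100 kb. Constant correlation matrices raise
an error rather than returning meaningless labels.

**Differential loops.** Size factors are library-size style: sample total
over the geometric mean of totals (`size_factor_method` is isolated should a
different convention be needed). Per loop, the two-group Poisson GLM with
log link and log-size-factor offsets has a closed form — each group's rate
is its count total divided by its size-factor total — which is computed
vectorially; agreement with an iteratively fitted GLM is asserted in the
test suite. Overdispersion φ is estimated from Pearson residuals and floored
at 1 (never below Poisson). With two or three replicates per condition a
purely per-loop φ has so few degrees of freedom that no reference
distribution is well calibrated: a normal reference is strongly
anti-conservative and a t(n−2) reference mildly conservative. The default
therefore pools Pearson statistics across loops of similar abundance
(trended dispersion over mean-quantile bins, ≤ 20 bins with ≥ 50 loops
each), which stabilizes the denominator enough for a normal reference —
empirically calibrated type-I error at the null (verified in the acceptance
suite). `dispersion_method="per_loop"` restores the per-loop estimate with a
t reference. Calls require p < 0.05 and |log2FC| > 1; loops below
`min_total` = 5 counts are reported untested; a group with zero total
receives a 0.5-count continuity correction and an `unstable` flag. Loop
confidence is filtered at FDR < 0.05 upstream of testing.

**APA.** For each loop whose pixel lies ≥ 2w+2 bins off the diagonal and ≥ w
bins from the matrix edge, the (2w+1)² submatrix (O/E by default) is
averaged; defaults w = 10 (21×21 window) at 10–25 kb resolutions. The score
is the center pixel over the mean of the (w//2 + 1)-sized lower-left corner
block — the corner nearest the diagonal, i.e. the P2LL convention, which
benchmarks the peak against the locally highest background and is therefore
conservative.

**SCC.** Both matrices are smoothed with a (2h+1)² mean filter (default
h = 1 at 100 kb); per distance stratum d (1 bin to `max_dist`, default 5 Mb)
the Pearson correlation is weighted by stratum size times the product of the
two stratum standard deviations. The zero-distance diagonal (self-contacts)
is excluded.

## The synthetic-data generator

The generator emulates the *downstream products* of the study design — never
raw reads — on toy chromosomes (a few Mb), with all randomness derived from
one seed through per-generator substreams (identical configs give
byte-identical output):

- **Time course** (default T = 6, mirroring sampling at days 0–15 in steps
  of 3): each locus draws a class from a mix (default 35% PO, 25% CO
  spread over k, 25% OC, 15% never-open), its ideal vector follows the class
  archetype, and observation flips each bit independently at `flicker_rate`
  (default 0.05, a plausible per-time-point peak-calling error). Label
  recovery is exact at flicker 0 and degrades with the rate, which the tests
  exploit.
- **Binding**: the serum-condition TF peak set is a strict subset of the
  ground-state set, emulating strongly asymmetric binding; specific peaks
  are split 25/19/56% over promoter/enhancer/intergenic placements
  (deterministic counts, so annotation recovery is exact); the motif
  consensus (a TEA-domain-like 8-mer) is written into bound peaks at an
  embedding rate of 0.8 over uniform-random sequence.
- **Expression**: five mean templates encode the C1–C5 verbal definitions;
  genes are assigned in fixed default cluster proportions
  (961/663/472/1101/1210), scaled by lognormal gene-level factors, and
  observed as means of two negative-binomial replicates at dispersion 0.05
  (variance = μ + 0.05 μ², a moderate bulk-RNA-seq level). The C5 template
  rises > 2-fold in WT by day 6 while the KO ratio stays ≤ 1.2.
- **Loops and matrices**: counts are negative binomial (gamma-mixed Poisson,
  the standard generative counterpart of a quasi-Poisson fit) at dispersion
  0.1 around lognormal baselines, with per-sample size factors log-uniform in
  [0.7, 1.4] and three replicates per condition. 20% of loops are planted
  decreased and 9% increased — a strong down/up asymmetry of the kind seen
  after losing a loop-anchoring factor — with magnitudes uniform in [1, 3] (down) and [1, 2.5] (up)
  log2 units, a spectrum rather than a point effect. Contact matrices carry
  power-law distance decay ((1+d)^−1), alternating compartment blocks
  (strength 0.6) with a planted 5% of bins flipped in condition B, and
  multiplicative enrichment (default 3×) at the pixels of the loops that fit
  on the 200-bin matrix chromosome (one bin per anchor, so planted anchor
  classes are unambiguous); loops beyond that capacity live on count-only
  chromosomes.

What the generator does **not** emulate: realistic sequence composition or
mappability, correlated/flanking loop signal (enrichment is single-pixel),
TADs and stripes, distance-dependent dispersion, batch structure, or any
read-level artifact. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative models — monotone switch patterns,
NB counts with planted effects, block compartments — not robustness to every
failure mode of real sequencing data.

## Problem sizes

The test and acceptance experiments run at desk scale, chosen so the whole
suite completes in seconds while estimates stay informative: 5,000 consensus
peaks for classification recovery; 2,000 loops at dispersion 0.1 and 3
replicates/condition for null calibration and planted-effect sensitivity;
200-bin matrices for compartments and balancing; the null-APA experiment
uses a deep (depth 500) matrix so single-pixel shot noise does not swamp the
aggregate; 1,000 genes for cluster recovery. Genome-scale peak and loop
counts (tens of thousands) require real sequencing data and are outside what
a synthetic desk-scale run reproduces; the worked-example percentages are
instead recomputed exactly at their reference numerator/denominator pairs.

## Known limitations

- Consensus building is presence/absence; no signal-level quantification or
  differential-accessibility testing.
- Binary peak specificity ignores sub-threshold signal; a pileup-based
  differential caller may disagree near thresholds.
- The enhancer definition is whatever BED the caller supplies; localization
  percentages depend on it entirely.
- The semantic C1–C5 mapping assumes the five canonical patterns are
  represented; with k ≠ 5 clusters are labeled generically.
- The differential loop test models counts per loop independently; no
  information sharing beyond the dispersion trend, no spatial dependence
  between adjacent loops.
- Compartment calls are per-chromosome and sign-oriented only by the
  supplied activity track; trans contacts and TADs are out of scope.
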