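# Methods

This note documents the models, parameters, and numerical choices behind
`te4c`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinate and data model

All in-memory coordinates are 0-based, half-open (BED convention); 1-based
conventions exist only at I/O boundaries. Restriction enzymes are data
(recognition site, cut offset): DpnII is `GATC` cut at offset 0, Csp6I
`GTAC` at offset 1. Genome sequences are restricted to `{A,C,G,T,N}` and
upper-cased on load; a recognition site never matches across an `N`
(conservative: an ambiguous base cannot be assumed to complete a site).

## Reduced genome

For every internal cut boundary, one upstream and one downstream flank of
25 bp (configurable, ≥ 10) is emitted when that many bases exist on its
side. A flank is *unique* — and hence part of the mappable reduced
genome — iff its exact sequence occurs exactly once in the whole genome,
counting both strands via reverse complement. This sequence-exact rule is a
deterministic proxy for unique alignability; it is implemented as a
vectorized 2-bit k-mer census (25 bp ⇒ 50 bits per k-mer), so uniqueness is
exact, not hashed. Flanks containing `N` are never unique.

## Bait design on a consensus

A bait candidate is an adjacent pair of primary-enzyme sites at least
300 bp apart with a secondary site at least 150 bp downstream of the
upstream primary site; both figures are treated as *minimum* distances
(the classical 4C design constraint) and are parameters. One candidate is
anchored per adjacent pair, reading from the upstream site rightward into
the fragment; the nearest qualifying secondary site is recorded.

The reading primer is deterministically the 20-mer whose 3′ terminus is the
end of the primary site. The second primer is chosen by exhaustive scoring
of every window of length 18–27 between the primary and secondary sites:
windows containing `N` or with GC outside [0.20, 0.80] are disqualified;
the remainder are ranked by |Tm − 60 °C| with ties broken toward the
shorter, then leftmost window, and the winner is reported as the reverse
complement (pointing back toward the reading primer). Tm is the Wallace
rule (2·AT + 4·GC) up to 14 nt and `64.9 + 41·(GC − 16.4)/len` above — a
deterministic estimator chosen so that identical inputs always give
identical primers; no nearest-neighbor thermodynamics, hairpin or dimer
screening is attempted (out of scope).

## In-silico PCR

A primer binds where its 3′-terminal block of 15 nt matches the genome
exactly and the remaining 5′ bases carry ≤ 2 mismatches (`N` counts as a
mismatch); both the protected-block length and the mismatch allowance are
parameters. The search seeds on the exact 3′ block, which is not a
heuristic: any qualifying site must contain it verbatim. Amplicons are
inward-facing +/− pairs on one chromosome with product ≤ 4000 bp (the
conventional in-silico PCR default). An amplicon is *on-target* iff it
overlaps an annotation of the target family and no other family; all pairs
from clustered matches are reported and deduplication is left to callers.

## Viewpoint ("observed bait") calling

Per-fragment counts are preprocessed in two steps: fragments overlapping a
blacklist are dropped; then fragments whose count is strictly above the
99.9% empirical quantile of the *nonzero* counts are dropped as
self-ligation/undigested artifacts. Ties at the threshold are retained, so
a flat count vector is untouched. Visualization tracks use 100 kb windows
stepping 25 kb (midpoint assignment) with values above the 75% quantile
capped to it; detection uses raw counts in 100 kb non-overlapping windows
(both window sizes are parameters — the 200 kb variant is a supported
configuration).

Each window gets `z = (x − μ)/σ` with μ, σ taken across all informative
windows of the genome (a window is informative iff ≥ 1 mappable reduced
fragment's midpoint falls in it; others are excluded from both fitting and
calling), a one-sided upper-tail normal p, and a Benjamini–Hochberg q
computed alongside. The 0.05 threshold is applied to the **raw p** by
default (`threshold_on="p"`; `"q"` is available). The rationale: at
synthetic scale the viewpoint windows are a non-negligible fraction f of
all windows and inflate σ, which caps attainable z near `1/√f`; an
insertion whose midpoint falls near a window boundary splits its mass
between two windows, each landing near `z ≈ 2`, below any BH threshold but
comfortably above 1.645. The same σ inflation makes the raw threshold
self-guarding — background windows sit *below* the contaminated mean, so
z > 1.645 is reached only by genuine viewpoint signal, and measured
recovery at the reference conditions is 15/15 planted sites with zero
spurious calls (the adjusted-value threshold recovers 10–14/15 because of
boundary splitting). The fit is on raw counts, not log counts: the decay
tails of neighboring viewpoints widen the log-scale null enough to destroy
detection.

Significant windows separated by ≤ 100 kb are merged; final regions must
overlap a merged region in *every* replicate, and the reported region is
the union hull of its supporting regions, with peak z the maximum window z
inside and p/q the smallest supporting values.

Two-set comparisons (observed vs predicted, strain A vs strain B) use
any-overlap: `shared` counts regions of one side overlapping the other,
with both sides' shared lists exposed (they coincide whenever the overlap
graph is one-to-one, as in all truth-matched simulations).

## Capture anchors and interactions

Pair ends are assigned to the restriction fragment containing their 5′
position; cis pairs with per-chromosome index difference strictly below
100 are removed (the filter models self-ligation and undigested products,
which are cis by construction, so trans pairs are never filtered), and
exact duplicates — identical canonical coordinate/strand tuples of both
ends — collapse to one, mirroring sonication-based duplicate removal.
Unique-read counts accumulate one per end; fragments strictly above the
`1 − 0.0005` quantile of all fragment counts are selected (strictly above,
so a flat vector yields no anchors), flagged by probe-target overlap, and
anchors not overlapping the target TE family are removed with the removed
count reported.

Probe targets are found by local alignment (match +1, mismatch −1, gap
open −2, gap extend −1) at ≥ 80% identity over ≥ 60 aligned columns;
*columns* include gap positions, otherwise gapped chains of short exact
matches in random sequence masquerade as high-identity hits. The genome is
scanned in 2 kb windows overlapping by twice the probe length and the best
local alignment per window is kept, so the procedure is exact for hit loci
separated by more than one window — which the simulator's ≥ 200 kb
insertion spacing guarantees; thresholds are configuration because the
original scoring scheme of the external aligner is not recoverable.

Scored interaction calls are an *import* (BEDPE with score in column 8, or
the ibed dialect recognized by its header); records below the 7.5 score
cut-off are dropped, the boundary value kept. The interaction-calling model
itself and downstream negative-binomial differential testing are out of
scope; the module exports per-interaction count matrices for external
tools and records the conventional thresholds (adjusted p < 0.01,
|log2FC| > 2) as metadata only. Per-anchor signal tracks count pairs with
one end in the anchor fragment into 1 kb bins stepping 500 bp across a
1 Mb region centered on the anchor midpoint; normalization across samples
uses median-of-ratios size factors over bins nonzero in every sample.

## Compartment and TAD context

Per chromosome: the contact matrix is distance-normalized by dividing each
diagonal by its mean (no smoothing — the minimal standard construction),
correlated across bin profiles, and the leading eigenvector of the
correlation matrix taken as the PC score. Bins with zero row sum are
masked throughout (NaN score, no label). The sign is oriented to correlate
positively with a user-supplied reference track (e.g. gene density); no
biological default is guessed. `PC > 0` labels compartment A.

Region PC values are coverage-weighted means over overlapped informative
bins; regions touching none are excluded from the positive-fraction
denominator. TAD membership of an interaction requires both end midpoints
inside one TAD interval — the midpoint rule makes border-straddling
fragments classify deterministically. Distances are absolute midpoint
differences, cis only.

## Permutation enrichment

Only the other end of each interaction is shuffled — the anchor is the
fixed viewpoint of the assay. Each iteration independently re-draws every
other-end's start uniformly on its own chromosome (length preserved,
clipped to bounds; shuffled intervals may overlap each other and need no
exclusion zones), expands by the ± 1 kb interaction flank, and counts ends
overlapping ≥ 1 feature interval. The empirical p is the fraction of
iterations whose overlap strictly exceeds the observed count: ties favor
significance, and p = 0 is reportable with no pseudocount. The strict
inequality makes the test slightly anti-conservative on very discrete
overlap counts; the calibration experiment therefore uses enough
interactions that the overlap distribution is fine-grained (measured null
rejection ≈ 2–4% at 0.05 over 200 runs).

Promoter contacts keep interactions with score strictly above 10, cis,
midpoint distance strictly below 5 Mb, whose flanked other end hits a
TSS ± 2 kb window; per-anchor counts are distinct promoters and
per-promoter counts distinct anchors. Genomic partitioning assigns each
other-end to exactly one of TSS (± 3 kb), gene body, or intergenic, with
TSS taking precedence so promoter-proximal signal is not double counted.

## The simulator

`simulate_te_genome` builds i.i.d.-uniform background chromosomes and
plants insertions with guaranteed spacing using an order-statistics
transform (sorted uniform draws plus fixed slots — pure integer
arithmetic, so byte-identical across platforms under a seed). Each
insertion draws a truncation class: full length; solo LTR (the 3′-terminal
`ltr_length` = 350 bp, a typical ERV LTR scale); or 5′-truncated with a
uniform truncation point — truncations are 5′-anchored so the 3′ end is
always retained, matching the empirical pattern of ERV integrations.
Substitutions are applied once per insertion at `mutation_rate` (default
0.02, within the divergence range of young ERV families), and the mutated
copy is shared by both strains carrying it. Each insertion is present in
both strains with probability `strain_shared_fraction` (default 0.7),
otherwise in one strain chosen at random. Insertions **replace** an
equal-length background segment rather than splice in, so coordinates are
identical across strains and every planted sequence is retrievable from
the emitted genome at its recorded interval; the truth table records the
retained consensus span, strain membership, and whether both
primer-matching segments are retained.

4C reads are background with probability `background_rate` (default 0.2,
uniform over mappable reduced fragments) and otherwise pick a
primer-retaining insertion uniformly and land on a fragment of its
chromosome with probability ∝ `(1 + d/s)^(−α)` (α = 1.5, s = 20 kb — a
standard contact-decay surrogate; cis only). Replicates differ only by the
seed stream. Capture pairs mix per-anchor decay pairs, planted-loop pairs
with mass proportional to loop strength, and uniform background; natural
duplicates are preserved because deduplication is the pipeline's job.

Default study sizes (chosen once as the package's reference conditions):
4 chromosomes × 5 Mb, 15 insertions, 2 replicates × 200k reads for
viewpoint recovery; 40 insertions at 70% sharing for the strain Venn;
10^5 fragments, 20 anchors, 300k pairs with the background rate set so
anchors carry ~50× the mean background fragment mass for capture
recovery.

**What the simulations do not emulate:** sequencing error and base
qualities, PCR amplification bias beyond natural duplicates, mappability
structure of real repeats (background is i.i.d. uniform, so nearly every
flank is unique — real genomes lose many flanks near repeats),
chromatin-state-dependent contact structure, or trans contacts beyond
uniform background. Passing tests therefore demonstrate the correctness
and calibration of the algorithms under their stated models, not
performance on real sequencing data.

## Numerical and degenerate-input conventions

Empirical quantiles are linear-interpolation quantiles throughout. A flat
window track (σ = 0) yields no viewpoint calls with a warning. Windows
with no mappable fragment, regions with no informative compartment bin,
and trans interactions in distance statistics are excluded rather than
imputed. BH adjustment is the statsmodels implementation, cross-checked in
the tests against an independent step-up computation; one-sided normal
tail probabilities come from scipy. All randomness flows through
`numpy.random.default_rng` seeded explicitly; seeds are mandatory in the
simulator and the permutation test.

## Known limitations

- Primer Tm is a deliberately simple estimator; designs should be re-scored
  thermodynamically before wet-lab use.
- The probe-target scan reports the best alignment per 2 kb window, so
  target copies closer than ~2 kb merge into one locus.
- The raw-p viewpoint threshold is calibrated for genomes where viewpoint
  windows contaminate the genome-wide fit; for genomes with thousands of
  windows per viewpoint the adjusted-value threshold (`threshold_on="q"`)
  is the stricter and preferable choice.
- `compare_bait_sets.shared` reports the one-to-one overlap count; for
  many-to-one overlap graphs the per-side shared lists differ and both are
  exposed.
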