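# Methods

This note documents the models, numerical choices and known limitations of
`nucdyn`. Coordinates are 0-based, half-open everywhere inside the
package; GFF3/SAM conventions are converted at the file boundary.

## Occupancy model

MNase digestion of chromatin leaves ~147 bp of nucleosome-protected DNA;
a sequenced read (or fragment) therefore marks one nucleosome, and the
fragment midpoint estimates the dyad. The occupancy chain is:

1. **Clonal filtering.** PCR duplicates appear as implausibly tall stacks
   of reads sharing (chromosome, 5′ end, strand). With λ the genome-wide
   mean 5′-end count per position, a stack is truncated to the largest k
   with P(X ≥ k | Poisson(λ)) ≥ cutoff (default 1e−10, configurable).
   Filtering is idempotent in practice because removal is rare at
   realistic depths; the bound is recomputed from the input of each call.
2. **Read adjustment.** Single-end reads are shifted 3′ by half the
   fragment size; paired fragments use their midpoint. Fragment size is
   estimated by cross-correlating '+'-strand 5′ ends against '−'-strand
   read ends over lags 100–250 bp (ties to the smaller lag); with
   noiseless fragments of length L the peak sits exactly at L.
3. **Footprint coverage.** occupancy(p) = number of adjusted positions
   within p ± w, with w = 73 bp (half a nucleosome) by default. The fixed
   footprint makes single-end and paired-end inputs comparable and centres
   signal on dyads; w = 0 degenerates to the positional histogram.
4. **Quantile normalization** over the concatenated all-chromosome
   vectors. Ties are resolved by *ordinal (stable) rank* by default: every
   sample then carries exactly the same sorted multiset of values, so the
   downstream mean − SD threshold is identical across samples by
   construction. The classical tie-averaging variant is available as
   `ties="average"`; it preserves within-sample tie equality instead of
   exact cross-sample multiset equality — the two properties are mutually
   exclusive for integer-valued coverage, and we prioritise the one the
   NDR thresholding relies on.

## Nucleosome calling and dynamics

Summits are occupancy local maxima strictly above the genome mean,
accepted greedily highest-first with ≥147 bp spacing (plateaus take their
midpoint); spans are summit ± 73 bp clipped at midpoints to neighbouring
summits. Fuzziness is the SD of adjusted read positions inside the span.
A consequence of the genome-mean height threshold is that weakly occupied
nucleosomes (roughly the bottom third at the default simulation depth) are
never called; the dynamic fraction denominator is the set of
reference-condition calls.

The **per-bp differential signal** between two normalized tracks is the
two-sided Poisson test p = min(1, 2·min(P(X ≥ b | a), P(X ≤ b | a))) with
a = max(occupancy_ref, 0.5) and b = round(occupancy_alt). This track is
reported per record (`min_bp_p`, the minimum over the record's span) and
is useful for visualisation, but it is *not* what feeds the FDR: treating
one condition's observed occupancy as an exact Poisson rate ignores its
own sampling noise and becomes strongly anticonservative at low coverage
(at ~18 reads per nucleosome, ~15% of null records would pass FDR 0.005).

Instead, each record's `p_value` combines three calibrated two-sample
tests on the adjusted reads inside the pair's union span, Bonferroni-
corrected across the three effect axes:

- *occupancy*: exact conditional binomial on the two read counts (success
  probability = the alternative library's share of total reads);
- *position*: Welch t-test on the read positions;
- *fuzziness*: variance-ratio F-test on the read positions.

Unmatched calls (present in one condition only) use the binomial test
alone on their own span — a call that is merely below the summit height
threshold in the other sample has similar read mass and is not reported
dynamic. Benjamini–Hochberg is applied across nucleosome records (not
base pairs) and records are retained at FDR < 0.005 when at least one
category effect-size threshold fires (fold ≥ 1.5, |Δsummit| ≥ 10 bp,
fuzziness ratio ≥ 1.3; dominance order occupancy > shift > fuzziness).

## NDR length

The NDR at a TSS or TTS is the longest maximal run of positions strictly
below the genome threshold (mean − population SD of the occupancy) whose
anchor-proximal border lies strictly closer than 65 bp to the anchor
(distance 0 when the anchor is inside the run); ties on length break
toward the nearer border, then leftmost. "Strictly below" and "strictly
closer" follow the literal reading; both are configurable
(`inclusive_offset`). ΔNDR = length(reference) − length(alternative), so
positive values mean shrinkage in the alternative condition; the extreme
deciles (⌈10%·n⌉ genes, id-tie-broken in opposite directions so the sets
stay disjoint under full ties) give the strongest-shrink/expand gene sets.

At ~18 reads per nucleosome the threshold crossing is noisy: the per-gene
null ΔNDR has sd ≈ 50 bp with occasional "run-through" tails where an
entire weakly occupied flanking nucleosome stays below threshold and the
measured NDR extends past it. Median ΔNDR over a gene set is robust to
this; single-gene deltas and rank-based selections (the deciles) are not,
which the test suite documents quantitatively.

## Meta-gene profiles and the −1 nucleosome

Profiles average occupancy over genes aligned at the strand-resolved TSS
or TTS (window ±1000 bp; negative offsets upstream in gene orientation).
The average −1 nucleosome is located on the smoothed profile (31 bp moving
average) as the *nearest prominent* upstream local maximum (prominence ≥
15% of the upstream dynamic range). Using the nearest rather than the
highest upstream peak is deliberate: for small gene sets the global
upstream maximum frequently lands on unaligned neighbouring-gene signal
several hundred bp away, whereas the −1 nucleosome is by definition the
first nucleosome upstream of the promoter NDR. The highest-peak behaviour
remains available (`mode="max"`). The −1 "shift" between conditions is
the difference of the two distances (positive = toward the anchor).

For small gene sets the averaged profile barely resolves −1 from −2: the
saddle between them is shallow (an 18 bp linker after 147 bp footprint
smoothing, further smeared by gene-to-gene NDR width variation), so the
profile-peak locator can jump a whole nucleosome. `per_gene_minus_one`
therefore measures, per gene, the distance from the TSS to the nearest
*called* upstream summit; the per-gene *median* of the cross-condition
difference is the robust estimate of the average −1 shift and is what the
recovery diagnostics report (the profile variant is reported alongside).
The median also absorbs genes whose −1 is called in only one condition
and therefore pairs a −1 with a −2 one nucleosome away.

## Promoter enrichment

The promoter window is −350..+50 bp around the TSS, strand-resolved,
boundaries inclusive. Each reference-condition call gets the strand-aware
offset to its nearest TSS (equidistant ties to the lexicographically
smaller gene id); the 2×2 table (dynamic × in-window) goes to a two-sided
Fisher's exact test with the probability-mass rule and the sample odds
ratio (inf/0 at zero cells; Haldane +0.5 optional). Degenerate windows
(every call on one side) and empty dynamic sets raise errors rather than
returning meaningless numbers.

## The synthetic generator

The generator emulates the statistical structure of a compact,
nucleosome-tiled genome: by default 2 chromosomes × 500 kb carrying 250
gene units. Each unit, in gene orientation, is two upstream nucleosomes
(−2, −1), a promoter NDR (width ~ N(140, 25²) bp, floored at 60), the +1
nucleosome and a phased body array at 165 bp spacing, a terminator NDR
(~ N(100, 20²)), and one downstream nucleosome; units abut with 20 bp
clearance so the genome is quasi-continuously tiled apart from the planted
NDRs. Per-nucleosome expected occupancy is Gamma-distributed (CV 0.3) and
dyad jitter is Gaussian (SD 20 bp, the scale of well-positioned yeast
nucleosomes). Fragments: nucleosome chosen ∝ occupancy weight, dyad
jittered, length from a truncated normal (mean 150, SD 15, bounds
[100, 250] bp — a mononucleosomal gel-purification size window), emitted
as one 50 bp single-end read on a random strand or as the whole fragment
in paired mode; 2% of fragments are uniform background so occupancy
thresholds are non-degenerate. A single seed drives truth construction
and per-condition sampling through separate derived streams; identical
config + seed gives byte-identical output files.

Perturbation classes are planted at disjoint gene sets, each comprising
`perturbed_fraction` (default 10%) of genes — the fraction is per class,
so the default study perturbs 40% of genes in total:

- **occupancy**: −1 expected occupancy × 2;
- **shift**: the promoter trio (−2, −1, +1) slides 40 bp coherently so the
  −1 approaches the TSS and the NDR length is unchanged. The slide is
  deliberately promoter-local; a known artifact is that the displaced +1
  can come within <147 bp of the first body nucleosome, which the caller
  then merges;
- **fuzziness**: −1 dyad jitter SD × 2;
- **ndr_shrink**: −2 and −1 slide 44 bp toward the TSS, shrinking the
  promoter NDR by exactly 44 bp in the truth tables.

What the generator does *not* model: sequence (no FASTQ, no MNase
sequence bias, no GC effects), replicate-to-replicate biological variance
beyond resampling, sub-nucleosomal particles, and transcription-coupled
occupancy gradients. Passing recovery tests therefore demonstrates that
the statistical machinery is correct and calibrated on an idealised
landscape, not that real libraries at the same depth would behave as well.

## Problem sizes and statistical power

Tests and the acceptance script run the default study at 100,000 fragments
per condition over a 1 Mb genome — about 18 reads per nucleosome. Three
recovery targets are *not attainable* at that depth and are reported as
measured rather than weakened:

- a ×2 occupancy change gives ~18 vs ~36 span reads; even the exact
  conditional binomial yields p ≈ 0.02, far above the ~1e−4 that BH at
  q = 0.005 over ~6000 records requires, so per-site sensitivity is near 0
  (≈6× the depth would be needed);
- the summit of a footprint-smoothed nucleosome is a midrange-like
  estimator with ~8 bp SD per condition, so per-site Δsummit lands within
  ±10 bp of a 40 bp planted shift for only ~half of recovered sites (the
  *meta-gene* shift, which averages over genes, recovers the planted value
  to a few bp);
- per-gene ΔNDR noise (sd ~50 bp) dwarfs a 44 bp effect for rank-based
  decile selection, though the *median* ΔNDR over planted genes is
  accurate.

Aggregated quantities — dynamic fraction, promoter odds ratio, median
ΔNDR, meta-gene −1 shifts, null-control calibration — are stable at this
scale, and those are the quantities the acceptance script reports.

## Degenerate inputs and tie-breaks (summary)

Empty read sets propagate as empty results; depth 0 is a valid simulation;
flat occupancy yields no calls and an explicit "no upstream peak" error in
−1 localization; a non-positive NDR threshold warns and returns 0-length
NDRs everywhere; equidistant call-to-gene assignment prefers the smaller
gene id; equal-length NDR runs prefer the nearer border, then leftmost;
decile ties break lexicographically (opposite directions per decile);
zero-valued bedGraph runs are written explicitly so round-trips preserve
vector length.
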