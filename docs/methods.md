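# Methods

## Junction model and read counting

Each AR transcript is keyed to a single discriminating splice junction,
represented as the coordinate pair `(donor_end, acceptor_start)`: the last
base of the upstream exon and the first base of the downstream exon,
1-based inclusive (SAM convention). The skipped intronic interval is
`[donor_end + 1, acceptor_start − 1]`. Coordinates are 1-based throughout
the public model; the half-open arithmetic of the CIGAR walk is internal.
Minus-strand junction definitions are normalised to the canonical
plus-strand orientation at load time, so counting has one internal
orientation.

A spliced alignment supports a junction when one of its `N` operations
skips *exactly* that interval (no coordinate slack; the assay's specificity
argument is exact exon-boundary identity) and the aligned (`M`/`=`/`X`)
reference coverage immediately flanking the skip is at least `min_overhang`
bases on both sides. Anchors are measured in reference bases: a deletion
terminates the anchor run (its reference bases are not aligned), while an
insertion — which consumes no reference — does not. Each read is credited
to at most one signature; signature uniqueness is enforced before counting
(two signatures with identical coordinates, the AR-V7/AR-V9 situation,
abort the run rather than silently double-count).

Parameter defaults, and why:

- `min_overhang = 6` bases. Small enough to retain junction reads from
  short reads, large enough to suppress 1–2-base spurious anchors from
  alignment slippage.
- `positivity_threshold = 1` spanning read. Positivity is presence/absence
  of the transcript signal; stricter floors are configurable.
- Any strand, no MAPQ floor, secondary/supplementary alignments excluded.
  These are stated defaults of this package, all configurable.
- Duplicate reads are not collapsed; deduplication is a documented
  limitation, not a hidden step.

The shipped exon model uses toy coordinates (nine 100-bp exons separated
by 100-bp introns on one synthetic 2,000-bp contig) because junction
counting depends only on boundary coordinates, not sequence. Real genome
coordinates are supplied via a tab-separated junction-definition file.

## ddPCR quantification

Droplets partition a reaction so that template counts per droplet are
approximately Poisson. With `n_pos` of `n_total` droplets positive, the
mean copies per droplet is `λ̂ = −ln(1 − n_pos/n_total)` and the
concentration is `λ̂ · 1000 / v` copies/µL for droplet volume `v` nL
(default 0.85 nL, the QX200 nominal; configurable). Copies/reaction is
concentration × reaction volume (default 22 µL), and copies/sample divides
by the fraction of the sample loaded. Per-CTC, per-ng and
reference-target normalisations are optional divisors, off by default,
because published experiments normalise differently per context.

Automatic thresholding finds the two-class 1-D partition minimising
within-class variance (exhaustive split over the sorted sample with prefix
sums — the 1-D k-means/Otsu optimum) and places the threshold at the
midpoint of the two class means. This is a transparent stand-in for
instrument software thresholds and is not claimed to match any vendor
implementation. A droplet is positive strictly above the threshold, so a
degenerate (constant-amplitude) well classifies all-negative.

QC rules: saturated wells (all droplets positive) carry no finite estimate
and are flagged `SATURATED`; wells under 10,000 accepted droplets are
flagged `LOW_DROPLETS`; an NTC with more than 2 positive droplets (a
common rain allowance) fails the plate, and sample wells on a failed plate
are flagged `UNRELIABLE` but still reported. Replicate CV uses the sample
(n−1) standard deviation; a zero mean leaves the CV undefined (flagged)
rather than infinite.

## Cohort statistics

Positivity is `copies > threshold` with threshold 0 (any detected signal)
by default; a missing measurement counts as not detected and is logged.
Cohort medians, means and ranges are computed over *all* subjects with
zeros included — a published range of the form "0–280" implies
non-detections enter the distribution as zeros. Prevalence is stored at
full precision and reported as a rounded integer percent.

The two-tailed Fisher exact test enumerates the full hypergeometric
support of the 2×2 table with fixed margins and sums the point
probabilities not exceeding the observed table's (the convention of
mainstream statistics packages). Probabilities are compared as integer
binomial-coefficient numerators over a common denominator, so tied tables
are included exactly, with no floating-point tie tolerance at all.

Mann–Whitney U uses midranks for ties. For pooled sample size ≤ 12 the
exact two-sided p enumerates all rank assignments and sums the probability
of |U − n₁n₂/2| at least as large as observed; larger samples use the
normal approximation with tie correction and a 0.5 continuity correction.
The crossover at 12 keeps exact enumeration ≤ 924 combinations. Group
expression comparisons operate on log2(count + 1); the +1 offset maps
zeros to zero.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, at
the study's stated conditions:

- **Droplets**: template counts Poisson(λ) per droplet; amplitudes
  Normal(8000, 300) for template-bearing and Normal(1000, 300) for empty
  droplets; default λ = 0.3 and 15,000 droplets/well. "Rain" converts a
  configurable fraction of *template-bearing* droplets to amplitudes
  uniform between the modes — rain physically arises from partial
  amplification of template-containing droplets, and drawing it from the
  positive class keeps truth labels meaningful. Midpoint thresholding of
  uniform rain still misclassifies about half of it, a first-order
  downward bias of `rain/2 · p/(1 − p)` on λ̂; the end-to-end recovery
  test budgets exactly that analytic term on top of 3 Monte-Carlo SEs,
  and rain-free recovery is asserted unbiased.
- **Spliced reads**: SAM text over the toy contig; junction reads have
  CIGAR `aM kN bM` with anchors drawn uniformly from the configured range
  and `k` equal to the signature's intron length; unspliced background
  reads are added at random positions. Sequences are a fixed filler
  pattern, since counting never inspects bases. A separate adversarial
  generator perturbs skip positions and lengths by a few bases and mixes
  in insertions, deletions and soft-clips for oracle-equivalence testing.
- **Cohorts**: each subject is positive per transcript independently with
  probability π (defaults 0.90/0.66/0.52 for AR-FL/AR-V7/AR-v567es over
  29 subjects, the published mCRPC prevalences); positive copies are
  log-normal with medians near 10/2/0.3 copies/sample (the published
  magnitudes) and σ = 1.5 for a heavy right tail; negatives are exactly 0.

What the generators do **not** model — and hence what passing tests do not
show about real data: sequencing and alignment errors, mapping ambiguity,
amplitude drift and plate effects, multi-channel crosstalk, droplet-volume
variation, within-subject correlation between transcripts, and
between-batch assay variation.

Because the study's per-patient source table is not redistributable, the
fixed 29-subject reference cohort shipped here
(`synthetic_mcrpc_reference_cohort`) is an explicit synthetic stand-in
whose per-transcript *marginals* (positives/29, median, mean, maximum)
match the published summary exactly; individual values carry no meaning.
It exercises the summariser's semantics (zeros included, rounding), not
the provenance of the data.

All generators draw from one explicitly seeded numpy `Generator` per call
and are bit-reproducible under a fixed seed.

## Problem sizes

Test and script workloads were sized for quick desk-scale runs: 100 seeds
per λ for estimator-recovery checks, 20×5 wells of 15,000 droplets for the
replicate-CV figure, 1,000 adversarial reads for oracle equivalence, 500
seeds for prevalence-recovery coverage. These sizes give Monte-Carlo
standard errors far below every asserted margin.

## Known limitations

- Exact-junction matching means small alignment wobble at the splice site
  (possible with real aligners) drops reads; a coordinate-tolerance flag
  would trade specificity for recall and is intentionally defaulted to 0.
- The automatic droplet threshold assumes two reasonably separated
  amplitude modes; heavy rain or overlapping modes degrade it.
- No read deduplication, no novel-junction discovery, no multi-channel
  crosstalk correction, and no survival/outcome modelling.
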