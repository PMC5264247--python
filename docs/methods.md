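# Methods

This note documents the models and conventions behind `straintrace`: what
each stage assumes, which parameters matter, what the synthetic cohort does
and does not emulate, and where the design was genuinely open.

## Strain observable and consensus reconstruction

The package's unit of observation is the *dominant-strain consensus*: for
each species detected in a sample, the per-position majority base over the
pileup of reads mapped to that species' marker genes. Markers are
species-specific by construction, so the pileup of a marker is (ideally) a
mixture of reads from the strains of one species, and the majority vote
recovers the most abundant strain.

Mapping is gapless seed-and-extend: an exact 21-mer match (either strand)
anchors a full-length ungapped extension, reported when identity ≥ 0.90,
with each read assigned to its single best placement (ties broken by
identity, then marker id, then offset, then forward strand — fully
deterministic). Gapless alignment is exact for the substitution-only data
the simulator produces and keeps the package self-contained; alignments
from a production mapper can be imported from SAM instead, and the rest of
the pipeline is agnostic to their origin.

Consensus calling masks a position with `N` unless depth ≥ `min_depth` (3)
and one base holds a strict plurality with frequency > `majority_frac`
(0.5). The defaults make masking behavior explicit and testable: depth 3 is
the smallest depth at which a majority is meaningful, and the strict-
majority rule guarantees the called base represents more than half of the
covering reads — the "dominant strain" contract. Raising `min_depth` can
only increase masking (tested as a monotonicity property).

A detection gate keeps noise out of strain comparison: a marker enters only
if ≥ 80% of its positions are unmasked, and a species only if at least half
its markers survive. These are package conventions, not claims about any
external profiler's internals.

## SNV rates, trees

Consensuses are concatenated at fixed reference coordinates (marker ids in
lexicographic order). Because the substitution-only model keeps every row
co-linear with the marker reference, *reference projection replaces de novo
multiple alignment* — a deliberate divergence from pipelines that re-align
extracted consensuses, chosen for exactness and testability.

The SNV rate between two rows is the mismatch fraction over jointly
unmasked columns, expressed per 100 columns; identity = 100 − rate. A
printed rate of 0.04 therefore corresponds to 99.96% identity. Pairs with
fewer than `min_columns` (1000) jointly unmasked columns are flagged
"insufficient overlap" and excluded from testing — a guard against spurious
0% rates from tiny overlaps. Rates are raw mismatch fractions; no
substitution-model correction is applied (the distances of interest are
within-species and small).

Trees are built by neighbor-joining on the rate matrix (branch lengths in
substitutions per site, i.e. percent/100), replacing likelihood-based
inference: at these divergences the additive-metric behavior of NJ is the
property that matters, and it is exactly testable (NJ recovers any additive
metric's topology and path lengths, verified to 1e-9 on random trees of
4–8 leaves). Ties in the Q criterion are broken by lexicographic label
order and negative branch estimates are clamped to zero, so trees are
reproducible. Serialization uses skbio's Newick writer.

## Transmission test

The package must decide whether a mother-infant strain pair is "too
similar to be consistent with" between-subject strain variation. No
standard test is fixed by convention here, so the null model is an explicit
design choice:

- Background: all SNV rates between subjects of *different* pairs for the
  species (reference strains, when projected in, count as additional
  background subjects).
- Null: under independent acquisition, the pair's SNV count over its n
  jointly unmasked columns is Binomial(n, p₀) with p₀ = min(background)/100.
  Taking the *minimum* background rate is conservative — the pair must beat
  the hardest plausible background.
- p-value: lower tail P(K ≤ observed). Verdict `transmitted` requires
  p < α/n_tests (Bonferroni over all tested pair-species, α = 0.05) *and*
  pair rate < min(background). If the background itself contains an
  identical strain (p₀ = 0) the test is not applicable and the verdict is
  `insufficient-data`.

Shared species use a strict > 0.1% relative-abundance threshold in **both**
members of the pair; relative abundance is estimated from mean marker depth
(a stand-in for a full taxonomic profiler, which is out of scope). The
cohort summary reports per-pair transmitted/shared fractions and their mean
over pairs.

Strain replacement (multi-timepoint cohorts): a pair-species transmitted at
an earlier timepoint whose later verdict is `not-transmitted` with pair
rate ≥ min(background) — i.e. the infant now demonstrably carries a
different strain. Because the earlier transmitted strain is the mother's up
to sequencing error, differing from the mother at the later timepoint
implies differing from the earlier infant strain as well. An untestable
later timepoint is reported `indeterminate`, never as replacement.

## Pangenome presence/absence

Strain presence is read off the sorted (descending) gene-family coverage
curve c(1..G): with m the median, the strain is present iff m ≥
`min_coverage` (1), c(⌈0.10·G⌉) ≤ `left_max`·m (1.70) and c(⌊0.90·G⌋) ≥
`right_min`·m (0.30). The three thresholds are the documented profiling
parameters; the placement of the two edge checks at the 10th/90th
percentile positions of the curve is this package's convention (the
original tool's exact edge definition is not published with the
parameters). Gene presence within a present strain uses the same
`right_min`·m cutoff, so one parameter family governs both calls; the edge
ratios are scale-free, making presence calls invariant to uniform coverage
rescaling (tested on 1,000 random curves). Profiles are clustered with
average-linkage hierarchical clustering under Euclidean distance (the
linkage is our choice; the distance is the documented one). Fewer than 10
families is reported not-evaluable.

## Normalized transcript abundance

NTA of a region = (RNA depth / total RNA reads) / (DNA depth / total DNA
reads): a sequencing-effort-invariant measure of transcription relative to
gene dosage. Regions with zero DNA depth have undefined NTA and are
excluded and counted — no pseudocounts, since silent smoothing would bias
fold changes. Species summaries normalize region NTAs by the species'
90th-percentile NTA; a species with > 90% zero-RNA regions (or a zero
normalizing percentile) is not evaluable. SD uses the sample (n−1)
convention. Between-species comparisons report the ratio of mean raw NTAs
as the fold change and a two-sided Mann-Whitney rank-sum p-value on the
region-level values (exact for small tie-free samples); the test choice is
ours, as no particular test is canonical for this comparison.

## Virome profiling

Breadth = fraction of reference positions with depth ≥ 1; average depth =
total aligned bases / genome length, averaged over *all* positions
including uncovered ones. These two definitions are fixed and used
everywhere. Consensus and SNV calling reuse the dominant-strain caller
(min_depth 3); reconstructed fraction is the non-N fraction. Mother/infant
variant sets are compared in consecutive 160-bp windows (terminal window
may be shorter); a position carrying different alternate bases in the two
samples counts once on each private side. Polymorphic sites — evidence of
haplotype coexistence — require depth ≥ 10 and minor-base frequency ≥ 0.2;
both thresholds are package choices calibrated so a 60:40 haplotype
mixture at 100× is detected at ≥ 9 of 10 variant sites.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes:

- **Cohort structure**: n mother-infant pairs sharing one species pool;
  per (pair, species) a transmission flag drawn with `transmission_prob`
  (default 0.14, the observed transmitted fraction of shared species).
- **Strains**: each subject's strain is derived from the species reference
  by substitutions at a divergence drawn uniformly from 0.6–2.6% (the
  observed between-subject range); transmitted infant strains equal the
  mother's up to `transmitted_divergence` (default 0 — residual mismatch
  then comes from sequencing error alone). Substitution counts are
  Binomial(L, d) with sites chosen without replacement and the substituted
  base always differing from the original.
- **Reads**: substitution-only, uniform start positions,
  ceil(depth·L/read_len) reads per sequence, per-base error rate 0.005 by
  default, constant Q37 qualities (an optional degraded-quality mode with
  mean < Q25 and sub-Q15 ends exercises the QC stage).
- **Abundances**: symmetric Dirichlet (α = 10) per sample; the expected
  marker depth of species s is abundance_s × n_species × `dna_depth`, so a
  uniform profile gives every species the configured fold-coverage.
- **RNA**: optional paired read sets whose per-species depth is
  additionally scaled by `rna_expression_multipliers`.
- **Sizes**: defaults of 3 markers × 1000 bp per species and 100-bp reads
  at 20× give each species ~3000 comparison columns — comfortably above the
  1000-column overlap gate while keeping full-cohort simulations desk-scale
  (a 20-pair cohort simulates and analyzes in well under a minute).

One integer seed drives every draw; identical configurations produce
byte-identical output files.

What the generator does **not** emulate: indels and structural variation,
amplification and GC bias, realistic quality-score profiles, co-abundant
strain mixtures within a subject (the dominant-strain mixture contract is
tested separately at the consensus level), host contamination beyond simple
decoys, and real marker catalogs. Passing the recovery tests therefore
demonstrates the statistical machinery is correct under the stated model,
not that real-data complications (mapping bias, paralogs, within-host
strain mixtures) are handled.

## Numerical conventions

- Coordinates are 0-based half-open internally, 1-based inclusive in all
  human-readable outputs (SNV tables, windows).
- Consensus ties (plurality or frequency exactly at `majority_frac`) mask
  to `N`; never resolved arbitrarily.
- The observed SNV count entering the binomial test is
  round(rate · n / 100).
- All randomized tests run under fixed seeds; property tests are
  derandomized.
- Pipeline outputs carry a 16-hex-digit SHA-256 prefix of the canonical
  JSON configuration; logs record record counts, not wall-clock times, so
  reruns are byte-identical.

## Known limitations

- The binomial null treats columns as independent; linkage between nearby
  SNVs makes the test anti-conservative in principle, mitigated by the
  conservative min-background p₀ and the hard rate-below-all-backgrounds
  requirement.
- With only one subject pair carrying a species there is no background and
  the species is untestable (`insufficient-data`) — matching the analysis
  logic, which needs cohort context.
- The gapless mapper is not suitable for real reads with indels; import
  SAM from a production aligner for such data.
- Direction of transfer (mother→infant vs the reverse) and independent
  acquisition from a shared environment are not distinguishable from
  strain identity alone.
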