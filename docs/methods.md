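# Methods

## Data model and conventions

The unit of analysis is an OTU (operational taxonomic unit, a 97 %-identity
16S rRNA cluster standing in for a bacterial species) in a count matrix of
OTUs × samples, with each sample assigned to one host species. Counts are
non-negative integers; every sample must have depth ≥ 1. Host labels are
lower-cased and stripped on input and otherwise compared verbatim.

**Presence** is raw count ≥ 1. No detection threshold is applied: the
presence/absence rules are stated in terms of occurrence, and introducing a
configurable floor would silently change every downstream count. Singleton
detections therefore count as presence; users who distrust singletons can
zero them out before loading.

**Relative abundance** is per-sample: count divided by the sample's total
reads over all OTUs in the input table. No rarefaction or other depth
normalisation is applied anywhere.

## Core filter

An OTU is retained iff it is present in strictly more than
`prevalence_threshold` (default 0.5) of the samples of at least one host
*and* exceeds `abundance_threshold` (default 0.005) relative abundance in at
least one sample. Both comparisons are strict (">", not "≥"), so with 37
samples "more than half" means ≥ 19, and exactly 0.5 % fails. The abundance
criterion is evaluated against the full input table's per-sample totals, not
against the retained subset, because the quantity of interest is the
fraction of total microbiota. When one host group should enter the
comparison only partially (for instance, only adult animals), the caller
passes an explicit sample-inclusion list; the filter never hard-codes such
restrictions. The filter is monotone in both thresholds and invariant to
row/column permutations.

## Abundance-based classifier (three hosts)

Rank tests cannot operate on zeros shared between groups in a meaningful
way at these sparsity levels, so zero counts are first replaced by
1/(sample depth) — the smallest abundance the sample could have resolved —
giving a strictly positive matrix. A provenance mask records which cells
were replaced.

Each of the three host pairs is compared with a two-sided two-group rank
test. For small samples without ties the exact rank-sum null distribution
is used; otherwise the tie-corrected (average-rank) normal approximation
without continuity correction, which is identical to a two-group
Kruskal–Wallis chi-square test. Significance is `p < alpha` strictly
(default alpha 0.01), with **no multiple-testing correction** — alpha is
per pairwise test, which is deliberate: the label rules are defined on raw
pairwise significance. The "higher" side of each pair is the group with the
larger median of zero-replaced abundance, falling back to mean rank on
median ties; an exact tie yields no direction and cannot support an
adapted/shared call.

The label rules, applied in this order to the three pairwise outcomes:

1. `adapted:h` — h significantly higher than both other hosts, regardless
   of the third pair's outcome.
2. `shared:h1+h2` — h1 and h2 each significantly higher than the third
   host, and h1 vs h2 not significant.
3. `non_adapted` — everything else. This covers: no significant pair;
   significant separation only between the extremes of the abundance order
   with both middle-involving pairs non-significant; and any residual
   pattern (e.g. a single significant pair involving the middle host),
   which has no coherent host interpretation and falls into the
   conservative sink.

Rules 1 and 2 are mutually exclusive by construction (an adapted host needs
both of its pairs significant; a shared pair needs its internal pair
non-significant), so every one of the 27 possible patterns (3 states per
pair) receives exactly one label; the test suite enumerates them. The rule
set is inherently three-host; other host counts are redirected to the
presence classifier.

## Presence/absence classifier and window profiles

For each OTU, `margin(h) = occurrence(h) − Σ occurrence(other hosts)`. If
any margin is positive (at most one can be), the OTU is adapted to that
host with strength equal to the margin; margin 0 is non-adapted ("> 0" is
required, not "≥"). Occurrences are *not* normalised by host group size:
the raw-sum rule is the intended statistic even with unequal group sizes,
and the per-host occurrence counts are carried in the output so that the
imbalance is visible.

Within each host's adapted block, OTUs are ordered by descending margin,
ties broken by descending occurrence in the focal host, then ascending
otu_id — the last two are this package's determinism choices, as is window
step 1. Sliding windows (default 8 OTUs) along each block, and along the
non-adapted block ordered by descending total occurrence, yield per-window
fractions of phyla or oxygen-survival traits; fractions sum to 1 per window
and unannotated OTUs count as `unknown`. Blocks shorter than the window are
skipped and simply produce no rows. For parity with heat-map style reports,
the presence table annotates each OTU's per-host mean relative abundance as
`low` (< 0.1 %) or `high` (≥ 0.1 %).

## Multi-host shared core

An OTU is in the shared core of a host set iff it is present in strictly
more than `core_prevalence` (default 0.5) of every listed host's samples —
e.g. a 9-sample host requires ≥ 5 occurrences. The conjunction makes the
core antitone in both the threshold and the host set, and with a single
host it reduces exactly to the prevalence half of the core filter. The
pipeline evaluates the core on the filtered OTU set over all hosts in the
table (including hosts excluded from the comparative classifiers, such as
an outgroup); the manifest records the host set used.

## Synthetic data generator

The generator emulates a multi-host faecal 16S survey. Defaults: hosts
human 44, pig 50, chicken 37, penguin 9 samples; per-sample depths
lognormal with median ≈ 3×10⁴ reads (bulk of the distribution within
10⁴–10⁵), floored at 1000. Planted classes: `adapted:<host>` (one focal
host), `shared:<h1>+<h2>` (two focal hosts), `ubiquitous` (all hosts) and
`noise` (no focal host). Per OTU and sample: presence is Bernoulli(π_in)
in focal hosts and Bernoulli(π_out) elsewhere (defaults 0.9 / 0.05); the
expected relative intensity is μ_in (focal) or μ_out (elsewhere; default
fold change 50) multiplied by a unit-mean Gamma(shape 2) factor for
overdispersion; counts per sample are multinomial at the drawn depth over
the per-OTU intensities, so column sums equal depths exactly — a
Dirichlet-multinomial-like model without fitting to any real dataset.
Oxygen traits are drawn per class (spore-formers at weight 0.7 among
ubiquitous OTUs, 0.1 in adapted classes, matching the qualitative pattern
that environmentally transmissible spore-formers dominate the shared
fraction) and taxonomy from a small fixed lineage pool with adapted classes
skewed toward Bacteroidetes and broadly distributed classes toward
Firmicutes. There is no phylogenetic signal beyond these class-level
frequencies. All draws come from a single `numpy` Generator; identical
specs (including seed) give identical output.

Two named configurations exist: a `three_host_benchmark` (3 hosts × 15
samples, 40 OTUs per planted class, π_in 0.95 / π_out 0.05, fold change 50)
used for parameter-recovery checks, and its matched `null_benchmark`
(fold change 1, equal π) under which every host-associated call is a false
positive.

What passing recovery tests does and does not show: the generator produces
independent OTUs with clean class structure and moderate overdispersion; it
does not emulate compositional coupling between taxa, sequencing batch
effects, chimeras, or host-specific depth biases. Recovery ≥ 90 % under the
benchmark demonstrates the classifiers' correctness and power at strong
contrast, not their behaviour on borderline real-world signals. Notably,
the presence margin is intentionally sensitive for sparse OTUs (an OTU seen
twice in one host and never elsewhere has a positive margin); in the full
pipeline the core filter removes such OTUs before classification, and the
planted `noise` class exercises exactly this interaction.

## Numerical and degenerate-input choices

- p-values are clamped to [0, 1]; the identical-groups case yields p = 1.
- Rank-test groups need ≥ 2 values; smaller groups are errors, not NaNs.
- A simulated sample in which every OTU is absent (possible only at extreme
  parameters) has its reads assigned to one uniformly drawn OTU so depth
  conservation and table validity hold.
- Ratios in the adapted:shared report are rounded to 2 decimals by
  round-half-even, with the raw integer numerator and denominator emitted
  alongside, so no information is lost to rounding; for each host the
  denominator counts that host's OTUs found in at least one other host
  (pairwise-shared labels involving the host plus the all-hosts-similar
  non-adapted class).
- The pipeline manifest stores the config snapshot, SHA-256 digests of the
  inputs and per-stage OTU counts, and deliberately no timestamps, so a
  rerun with identical inputs is byte-identical.

## Known limitations

- The abundance rule engine is fixed at three hosts; generalising the
  significance-pattern rules to k hosts is out of scope (the presence
  classifier covers k ≥ 2).
- No effect sizes or FDR control are reported for the pairwise tests — the
  classifier is a rule engine over significance booleans, by design.
- Occurrence-based statistics ignore group-size imbalance (see above).
- BIOM support covers the JSON (1.0) dialect only, not HDF5 (2.x).
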