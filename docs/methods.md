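# Methods

## Data model and scales

All computation happens on an OTU × sample matrix with a sample-to-group
map. Internally relative abundances are **proportions** (each sample
column sums to 1 ± 1e−9); every *reported* abundance statistic — core
tables, SDRA values, thresholds — is on the **percent scale**, converted
only at the API/report boundary. This convention makes the bundled
reference tables exactly reproducible: their printed relative abundances
(e.g. 0.0334) are percentages, and summing the W membership rows gives
the quoted 0.1976 % without rounding tricks. Reports print abundances to
4 decimals, matching the usual presentation of core tables.

Mode inference on input tables is best-effort (all-integer → counts,
column sums ≈ 1 → proportion, ≈ 100 → percent, otherwise free
non-negative weights treated as counts) and can always be overridden
explicitly — small or summary tables are genuinely ambiguous.

Identity is always the OTU ID; duplicate taxonomy labels across distinct
OTUs are expected (two *Pseudarthrobacter* sp. OTUs appear in the same
core table) and never merged.

## Per-group summaries

For each OTU within one group of *n* samples:

- `mean_ra` = 100 × mean proportion;
- `sd_ra` (SDRA) = 100 × standard deviation of the proportions. The
  **sample SD (ddof = 1)** is the default: with only four samples per
  group the n vs n−1 choice is material, so it is explicit and switchable
  (`sd_ddof ∈ {0, 1}`). A one-sample group gets SD 0 by convention (the
  composition method refuses such groups outright).
- `prevalence` = fraction of samples with proportion > `presence_epsilon`
  (default 0: any detection counts — "shared by all samples" means
  detection, not an abundance floor; the epsilon exists for noisy
  pipelines).

## Core definitions

Both taxonomic methods restrict candidates to the group's **shared** OTUs
(prevalence exactly 1.0) — the composition method builds on the
membership analysis rather than on the full table, which is why
composition cores can contain OTUs outside the membership top-10.

- **Membership**: sort shared OTUs by `mean_ra` descending, ties broken
  by natural OTU-ID order (OTU2 < OTU10) for determinism; keep the first
  `top_n` (default 10).
- **Composition**: keep shared OTUs with `sd_ra` **strictly** below
  `sd_threshold` ("lower than" reads as `<`). The default threshold 0.01
  is interpreted on the percent scale — the scale on which core tables
  print their ± SD columns, and the only reading under which a published
  candidate table's internal logic (±0.0033 retained, ±0.1780 excluded)
  is self-consistent; `threshold_scale="proportion"` is available.

On the bundled W candidate table this rule retains 8 of 10 rows. The
source study's prose reports *five* composition-core members for each
forecrop, which is inconsistent with its own printed rows (8 pass for W,
0 for L, where the smallest printed SD is 0.0129); likewise its
composition-core totals (6.425 % / 4.253 %) do not equal the sums of the
printed rows. The implementation follows the stated rule and the printed
rows; no attempt is made to reverse-engineer the intended five. Similarly
the L membership rows sum to 0.2009 % while the prose quotes 0.2006 %;
the rows win.

`overlap` partitions two cores by OTU ID into shared / unique-to-A /
unique-to-B, ordering shared members by the first core's abundance
ranking. It is pure set algebra and works across methods and groups
alike.

## Functional assignment

The rule file dialect follows the FAPROTAX flat-file convention: an
unindented header opens a function (name, tab, metadata), indented lines
carry one taxon pattern each, `#` comments, and `add_group:other`
includes another function's clauses (resolved acyclically; cycles and
undefined references are parse errors; clause-less rules are dropped with
a warning). Patterns are case-sensitive with a greedy `*` wildcard and
must match the *full* semicolon lineage path or a *full* single rank
name — substring matches without wildcards do not count.

A small bundled rule set (12 functions over the genera typical of wheat
rhizosphere cores) lets everything run without downloads; a full
FAPROTAX release parses through the same reader.

Functional profiles are **presence-based**: the denominator is the
group's detected OTUs (> 0 in ≥ 1 sample), the numerator those assigned
to the function; functions are not mutually exclusive, so percentages
need not sum to 100. Wholly unclassified OTUs are never assigned — rule
databases describe characterised strains, so only identified taxa enter
the functional core. Abundance values never influence the percentages.

Group comparisons use **Fisher's exact test** (two-sided, via
`scipy.stats.fisher_exact`) on the 2×2 table of assigned/not-assigned
counts: exact at the small OTU counts involved, and the original
analysis's test is not recoverable. A pooled two-proportion z-test is
available (`test="ztest"`) for large-count use. The test suite checks the
Fisher p-values against an independent `math.comb` hypergeometric
enumeration to 1e−10 for totals ≤ 50.

## Synthetic communities

The generator emulates the study design the methods assume: 2 groups (W/L) × 4
samples, depth 5,000 reads per sample (the order of the study's
4,200–5,000 per-sample totals), 10 planted core taxa per group over 90
patchy peripherals. Expected proportions are lognormal — the standard
null for amplicon communities, since no distribution is stated by the
source — and observed counts multinomial at the given depth, so columns
sum exactly to the depth:

- core taxa: between-taxon base `exp(N(log 0.01, 0.3))`, per-sample
  mean-one lognormal jitter with CV 0.2 (ubiquitous, low variance);
- peripheral taxa (and the other group's core taxa, which behave
  peripherally outside their group): present per sample with probability
  0.5, abundance `exp(N(log 0.001, 1.0))` — one order of magnitude below
  the core.

The 0.3 / 0.2 / 1.0 dispersion defaults were chosen once as realistic for
rhizosphere amplicon data: tight enough that the planted core is
ubiquitous at depth 5,000, loose enough that occasional peripherals reach
full prevalence and compete for top-10 slots. Randomness comes from one
`numpy.random.default_rng` (PCG64) seeded from the spec; identical specs
reproduce identical tables. The truth record lists planted core IDs per
group and warns when the depth cannot represent the core (< 1 expected
read).

What the generator does **not** emulate: taxonomic misclassification,
chimeras, compositional correlations between taxa, overdispersion beyond
lognormal-multinomial, or a real forecrop effect (a multiplicative group
shift is the natural extension but is off by default). Passing tests
therefore demonstrate correctness of the *methods* under a clean
abundance-occupancy structure, not robustness to real sequencing
artefacts.

Note that at the default noise level the planted core's SDRA (~1 % for a
~5 % taxon at CV 0.2) sits far above the 0.01 % composition threshold:
on synthetic data the composition core is empty unless the threshold is
raised toward the realised SDRA scale. That mirrors how sharply selective
the published threshold is.

## Reference fixtures

The four published per-group summary tables (top-10 membership cores for
W and L; composition candidates with mean ± SD for W and L) are encoded
verbatim as structured records. Because the underlying per-sample matrix
was never published, `fixture_sample_table` reconstructs a synthetic
4-sample proportion table per fixture: each tabulated OTU gets four
values with the exact printed mean (and, where printed, the exact sample
SD, via symmetric offsets ±1.5σ̃/±0.5σ̃ normalised to unit sample SD);
four "filler" OTUs, each absent from exactly one sample, absorb the
remaining column mass so every column sums to 1 while staying out of the
prevalence-1 candidate set. The methods applied to these tables reproduce
the printed summaries to float precision.

## Pipeline and determinism

`run_pipeline` executes load → normalise → membership + composition cores
per group → overlaps (membership across groups; membership vs composition
within each group) → functional profiles and pairwise Fisher comparisons,
writing TSV reports and a `summary.json`. Any stage failure aborts with
the stage name; reruns with the same config are byte-identical (the
optional timestamp header is off by default). Problem sizes throughout
the test suite (tables ≤ 20 × 4 for oracle comparisons, 100 seeds × 110
OTUs × 8 samples for recovery) were chosen as comfortably sufficient for
the statistical checks while keeping the whole suite a few seconds long.
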