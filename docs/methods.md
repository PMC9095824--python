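# Methods

## Haplogroup model and calling

The tree is a rooted hierarchy of haplogroup labels; each branch carries
the substitutions (1-based rCRS coordinates, SNPs only — the panel
technology assays point variants, so indels and heteroplasmy are out of
scope) that define it. A haplogroup's *expected profile* is the state
per position after applying every variant on the root-to-node path in
order; a `!`-suffixed token is a back-mutation and restores the
ancestral base, so an expected state may equal the reference and then
does not count as derived.

Calling uses the Kulczynski similarity: the mean of recall over the
haplogroup's expected derived states and precision over the sample's
observed derived calls, both restricted to panel positions with a
non-missing call, with 0/0 := 1. Rationale for the conventions:

- **Missing calls are excluded from every term.** Panel dropouts are
  uninformative; treating them as reference calls would systematically
  pull assignments toward the root.
- **No explicit genotyping-error model.** With ~115 sites per sample
  there is too little data to fit an error likelihood; spurious derived
  calls are penalised through the precision term only.
- **Ties resolve to the deeper label, then lexicographically.** When a
  terminal branch's defining sites have all dropped out, parent and
  child score identically; the caller prefers the more specific label
  and records the tie-break rule in report metadata so users who prefer
  conservative (ancestral) assignment can see which rule produced the
  output. The search is an exhaustive argmax over all nodes — at tree
  scale (tens to thousands of nodes) pruning is unnecessary.

A sample with no evaluable panel position raises an error rather than
returning an arbitrary score.

The packaged tree is a **curated stand-in**: 63 nodes covering every
haplogroup the regional classification references, with the well-known
defining positions on the deep branches (M, N, R, U) and synthetic but
internally consistent positions elsewhere, arranged so the union of
defining-variant positions is exactly the 115-site default panel
(pools of 23, 36, 31, 25). Production analyses should supply the full
published tree and the laboratory's own panel file; both are plain-text
inputs.

## Regional ancestry

Classification rules are label lists with range (`M30-M67`) and
letter-suffix (`U2a,b`) shorthand. A rule matches a haplogroup when its
label equals the haplogroup's label or any ancestor's; the most specific
match (longest matching label) wins, which is what makes sub-clade
carve-outs such as U2a/U2b (South Asian) meaningful inside the broader
west-Eurasian U1–U5 rule. The east-Eurasian "A-G" entry is read as the
alphabetic macro-clade list A, B, C, D, E, F, G — range semantics over
letters are undefined, and these seven are the intended clades.
Unmatched haplogroups are counted as Unclassified so region fractions
always sum to 1.

Enrichment of a focal region between two cohorts uses Fisher's exact
two-tailed test (scipy) on the 2×2 focus/non-focus × cohort table; the
two-tailed p is the sum of probabilities of all tables at fixed margins
no more probable than the observed one. Fisher is preferred over a
normal approximation because region counts at cohort sizes of tens are
small. Published reference data are frequency tables, not raw counts, so
cohort-vs-reference comparisons in the pipeline scale each reference
population's region fractions to `reference_n` pseudo-individuals
(default 50, matching typical published sample sizes); the resulting
p-values are indicative, not exact, and the parameter is a config key.

## Population structure

PCA is classical covariance PCA computed by SVD of the column-mean
centred population × haplogroup frequency matrix. Frequencies are left
unscaled: they already share a scale, and per-column standardisation
would inflate noise from rare haplogroups. The cohort is an active row,
not a post-hoc projection. Eigenvalues use the n−1 divisor; the sign of
each component is fixed by making its largest-magnitude loading
positive, so coordinates are reproducible across platforms. A constant
matrix yields zero eigenvalues and coordinates rather than an error.

## Isotopes

Drinking-water δ¹⁸O is back-calculated by inverting the enamel-carbonate
calibration δ¹⁸Oc = 0.77·δ¹⁸Odw + 28.1 (‰ VSMOW). Values are kept at
full precision internally; only the reporting layer rounds to 1 decimal,
so rounding error never accumulates through downstream steps. QC
plausibility windows (carbonate 15–35 ‰, carbon −25 to 5 ‰) reject
pathological inputs before conversion.

Locality: a sample is consistent with a region when its drinking-water
value lies in the region's closed water interval widened by a tolerance
(default 0.5 ‰, a flag) that absorbs analytical error and seasonal
spread; it is local when the designated local region is among its
consistent regions. The packaged regional ranges (Punjab −9.0 to −6.5,
Gangetic plain −6.5 to −3.5, coastal −3.5 to −1.0 ‰) are **illustrative
editable config**, not measured truth — users must substitute ranges
with documented provenance for their study area.

Diet: bioapatite carbonate is enriched over diet by roughly 9–15 ‰; the
midpoint (+11.5 ‰) applied to diet end-members of −26.5 (C3) and −12.5
(C4) ‰ gives the default enamel end-members −15.0 and −1.0 ‰ VPDB. The
C4 fraction is the linear mixing coordinate, clipped to [0, 1], and
classed C3-dominant (< 0.25), mixed (0.25–0.75, boundaries inclusive) or
C4-dominant (> 0.75). End-members and enrichment are config.

Known numerical quirk: applying the inversion to a carbonate value of
21.4 ‰ yields −8.701… → −8.7 at 1 decimal, while −8.8 is sometimes
quoted for that endpoint in the literature this package follows; the
package reports the value its own equation produces.

## Synthetic data

The generator exists so every stage is testable without downloads; all
randomness flows from one explicit seed through `SeedSequence` spawning.

- **Genotype cohorts**: haplogroups drawn from a distribution whose
  default realises a 50-sample north-Indian cohort (M39 0.24, R32 0.14,
  HV0e 0.06, U3 0.02, U7 0.02; macro-M mass 0.70); calls equal the
  expected panel profile, then per-call dropout (default 10 %) and
  uniform substitution error (default 0) are applied. A truth table is
  emitted for scoring.
- **Reference frequencies**: 14 populations on a 1-D west→east
  coordinate; each population's west-Eurasian mass follows a linear
  cline from 0.45 to 0.03 exactly, split within haplogroup pools by a
  Dirichlet draw (concentration 40) so rows sum to 1 while pool totals
  are deterministic.
- **Isotopes**: drinking water per region Gaussian (Punjab −7.75 ± 0.5,
  Gangetic −5.0 ± 0.6, coastal −2.2 ± 0.5 ‰, matching the packaged
  ranges), pushed through the *forward* carbonate calibration plus
  analytical noise (0.15 ‰); carbon via the forward mixing model from a
  clipped-Gaussian C4 fraction (0.35 ± 0.2).

What passing on synthetic data does **not** show: the generator draws
genotypes exactly from tree profiles (no homoplasy, no aDNA deamination
damage, no contamination), its frequency tables are smooth Dirichlet
draws rather than real drifted populations, and isotope values ignore
altitude, seasonality and breastfeeding enrichment. Results on real
data depend on the quality of the user-supplied tree, panel, reference
frequencies and water ranges.

## Problem sizes used by the test suite

Recovery and oracle checks run on seeded cohorts of 40–500 samples over
the 63-node packaged tree; the Fisher implementation is checked against
exact rational enumeration over all ~2.5·10⁵ tables with row sums up to
30; PCA oracles use 6–12 populations × 4–8 haplogroups. These sizes make
the full suite run in about two minutes on one core while still
exercising every degenerate branch (all-missing samples, constant
matrices, boundary intervals, 0/0 score conventions).
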