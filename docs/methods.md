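# Methods

This note documents the models, rules, parameter defaults and numerical
conventions implemented in `barcodeflora`, the design choices made where
several defensible options existed, and what the synthetic benchmarks do
and do not demonstrate.

## 1. The inference problem

A species present today in a recently deglaciated coastal flora (the
package's motivating case is Churchill, western Hudson Bay, ice-covered
until ~10 ka BP) must have colonized from one of the two contiguous source
floras, the North Atlantic or the North Pacific. The *likely source region*
(LSR) question is strictly about this post-glacial migration — not about a
lineage's deeper phylogeographic origin. The evidence is a set of aligned
DNA barcodes (COI-5P for Rhodophyta/Phaeophyceae, *tufA* or *rbc*L-3P for
Ulvophyceae) from the focal region and from both candidate source regions,
plus a morphology-based regional checklist.

## 2. Distances

Observed proportions of differing sites use **pairwise deletion**: a site
enters a pair's comparison only if both characters are unambiguous bases
(A/C/G/T); gaps and IUPAC ambiguity codes are treated identically as
missing. The Jukes–Cantor correction

    d = −(3/4) · ln(1 − 4p/3)

is applied per pair. The original analyses this package formalizes were run
in an interactive tree viewer whose deletion policy is unrecorded; pairwise
deletion is the least-surprising standard convention, and is stated here so
results are reproducible bit for bit. Observed p ≥ 0.75 raises a
`SaturationError` rather than returning a sentinel: barcode-scale data
should never saturate, so silence would hide an upstream fault (a
misaligned or non-homologous record). Distances are stored as proportions;
"percent divergence" is presentation only.

## 3. Delimitation

UPGMA (unweighted average linkage) is implemented directly with the
documented tie-break — among equidistant candidate pairs, the pair whose
smallest member id sorts first merges first — so output is independent of
input order. Heights are stored as distance/2; all thresholds are quoted on
the distance scale (cophenetic distance = 2 × merge height), matching how
barcode divergences are conventionally reported. The test suite checks the
implementation against an independent naive average-linkage reference and
against `scipy.cluster.hierarchy` cophenetic matrices.

`cut_tree` forms groups as maximal subtrees whose internal cophenetic
distances are strictly below the threshold, with one deliberate exception:
zero-height merges (identical sequences) always co-cluster, so a threshold
of 0 yields one group per distinct sequence rather than per record.

**Species threshold, default 0.01 (1 %).** No printed cutoff exists for the
survey the package encodes; the choice is constrained on both sides by
published divergences — within-group diversity runs 0–0.8 % while
candidate-species splits start at ~1.2–1.4 % — and 1 % separates those
bands. It is configurable per run (`ClassifierConfig.delimit_threshold`),
and borderline complexes (groups 1.4–2.2 % divergent) are genuinely
threshold-dependent; the package documents rather than resolves that.

**Population threshold, default 0.004.** Used only to delineate regional
mitotype sub-clusters inside a species group when no fixed differences
exist. Fixed-difference evidence takes precedence over sub-cluster evidence
whenever both are available.

## 4. Mitotype structure

For a group containing both Atlantic and Pacific members,
`within_group_structure` scans for **fixed differences** (site-level
complete deletion: a column counts only if every member of both partitions
is unambiguous there; fixed iff both partitions are monomorphic for
different bases). Each Churchill sequence is then scored by the diagnostic
states it carries: all-Atlantic states → `matches_atlantic`, all-Pacific →
`matches_pacific`; specimens split between the two signatures →
`matches_both`; any sequence matching neither → `unique`. Without fixed
differences the sub-cluster route is consulted; failing both, the group is
`undifferentiated`.

For a group containing only one source region, the structure records fixed
differences between the Churchill members and that region. Churchill is
"nested" when fewer than `min_fixed_elim = 2` fixed differences separate
it; at 2+ the sampled region is treated as positively excluded as a source.
The threshold of 2 sits between the one-fixed-difference cases the encoded
survey scores as *matching* (weak population signal) and the three-fixed-
difference case it scores as *excluding* the sampled region.

## 5. The LSR rule engine

Each species receives at most one call per basis, with the firing rule id
recorded for audit.

**Morphological basis** — uncertain if presence (reported in the checklist
*or* observed among barcoded specimens) covers both oceans, if the
morpho-species maps to more than one genetic group in either source region,
or if the name is flagged for taxonomic confusion; otherwise the single
region of presence.

**Molecular basis** — ordered cascade over the Churchill-containing
group(s):

- **R0** external-evidence override: a secondary marker (ITS, *rbc*L)
  assigns the Churchill population to a regional lineage. Used only where
  the barcode data alone cannot reach the published call; the encoded panel
  carries exactly one such override.
- **R1/R1P** the Churchill barcodes share a group with exactly one region,
  nested among its mitotypes, and the other region is unreported,
  adequately screened, or positively eliminated → that region.
- **R2** the group spans both regions with ≥ 1 fixed difference; the
  Churchill signature decides: atlantic / pacific / both (split
  signatures) / uncertain (unique mitotype).
- **R3** the group spans both regions without geographic differentiation →
  uncertain (recent migration, direction unknowable from these data).
- **R4** elimination: the sampled region is positively ruled out — its
  conspecifics (n ≥ `min_conspecific_elim = 5`) all fall in other groups,
  or the Churchill members are separated from it by ≥ `min_fixed_elim`
  fixed differences — leaving the reported alternative as the call.
- **R5** no usable comparator signal → uncertain.
- **R6** two single-region groups in *opposite* regions each contain
  Churchill members → established from both oceans. (Ambiguous multi-group
  placements — e.g. two groups that each span both oceans — resolve to
  uncertain, rule RX, never to a region: the engine demands positive
  geographic concordance.)

**Eligibility.** A species is excluded from the summary exactly when its
molecular evaluation is blocked by a candidate source region that has no
conspecific barcodes and no adequate comparator screen, and no positive
elimination rescues the call. Adequacy defaults to a heuristic —
conspecific n ≥ 5 or a congeneric/confusable-taxon screen of n ≥ 20 — but
an explicit per-species flag overrides it in either direction. This
reflects how such judgments are actually made: a deep congeneric screen is
informative for a species that could hide under congeners, and useless for
a morphologically distinct one. The encoded panel sets explicit flags for
the handful of species where the published judgment departs from the
heuristic, and the flags are data, not code, so synthetic runs remain
purely rule-driven.

Sensitivity analyses can disable rules (`ClassifierConfig.disabled_rules`);
a disabled rule degrades its species to uncertain rather than flipping the
call, and eligibility ignores disabling so the denominator is stable.

## 6. Summary arithmetic

Two denominators are kept explicit: shares of *included* species, and
shares among *assigned* species only (atlantic/pacific/both; "both" counts
as assigned). Percentages round half-up, to the nearest integer by default
and to one decimal in checklist-style summaries — the convention that
reproduces every published figure the panel encodes. Scenario analysis
re-derives the assigned-only share after adding species (excluded or
never-barcoded taxa given a hypothesized source) and reassigning uncertain
ones; a scenario region of `other` puts a species in the denominator
without crediting the queried region, which is how "half of these species"
scenarios are expressed.

## 7. The synthetic-flora generator

The generator emulates what the analysis consumes — aligned barcodes whose
pairwise distances and diagnostic sites carry a geographic signal — using
per-site independent Jukes–Cantor substitution rather than a coalescent
simulator. That is a deliberate simplification: the pipeline only reads
pairwise distances and site patterns, so genealogical realism would add
cost without changing what is tested. Per-branch substitution probabilities
invert the JC correction (p = (3/4)(1 − e^(−4d/3))), which makes the
per-site process exactly the JC Markov chain, so realized JC distance
estimates are unbiased for the requested divergence and compose correctly
across branches.

Defaults (chosen once, as the study conditions): 664 sites (COI-5P barcode
scale); between-ocean divergence `d_between = 0.02` (inside the observed
1.2–3.3 % band for recently isolated populations); within-population
diversity `pi_within = 0.002` and Churchill-from-source divergence
`d_churchill = 0.002` (the observed 0–0.8 % band); five barcodes per
region; a scenario mix mirroring the observed flora composition (0.37
atlantic-source, 0.10 pacific, 0.02 both, 0.08 churchill-unique, 0.08
undifferentiated, 0.35 excluded-no-comparator). Named presets bracket the
printed divergence regimes: `washingtoniensis-like` (shallow divergence,
high within-species diversity), `chordaria-like` (d ≈ 0.027),
`undifferentiated` (d = 0), and `separated` (the well-separated benchmark
regime, D ≥ 0.015, π ≤ 0.003).

Reproducibility: one `SeedSequence` per flora is spawned into independent
per-species streams, so a species' draws do not depend on flora size or
ordering, and identical parameters + seed give byte-identical output files.

**What passing synthetic benchmarks shows — and does not.** The recovery
experiments (molecular LSR accuracy ≥ 95 % over 200 separated-regime
floras of 10 species; ≥ 99 % uncertain under the undifferentiated regime)
demonstrate that the rule engine recovers the truth when the data meet its
assumptions: star-like within-population genealogies, region-monophyletic
lineages, no recombination or introgression, equal sampling. Real barcode
surveys violate several of these (incomplete lineage sorting, uneven and
opportunistic sampling, human-mediated introductions), so synthetic
accuracy is an upper bound, not a field error rate. The flora sizes above
are the package's benchmark conditions; they are configurable.

## 8. Numerical and format conventions

- Column indices in fixed-difference reports are 0-based.
- Newick output gives branch lengths summing root-to-tip to the root merge
  height; a single leaf is written `(A:0);` for parser compatibility.
- FASTA record ids are the first whitespace-delimited header token;
  duplicate ids and non-ASCII ids are errors (ids key the metadata join).
- The Ulvophyceae markers (*tufA*, *rbc*L-3P) are clustered independently;
  whether the original analyses pooled them is unknowable, and the
  independent treatment is recorded as a divergence from an unrecorded
  original.
- The encoded panel splits one published combined count (the two cryptic
  groups under a single *Polysiphonia* morpho-species share a printed
  Atlantic total) into per-group counts; the split is flagged as synthetic
  in the panel's note column and only the combined total is documented.

## 9. Known limitations

- Group boundaries for complexes whose divergence straddles the threshold
  are threshold-dependent by construction; the package reports, not
  decides, such cases.
- The barcode markers are species-level markers; population-level
  resolution (and hence R2-type calls) is limited by their variability.
- Confidence is not quantified: calls are categorical with a rule-id audit
  trail, matching the source methodology, and no interval accompanies the
  percentage summaries.
- External-evidence overrides are modeled as flags with citations; the
  secondary-marker alignments themselves are out of scope.
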