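# Methods

## Scope and data model

`rlenet` analyzes product-mediated enzyme inhibition. Its inputs are four
tab-separated tables: an enzyme table (EC number, organisms carrying a gene
for the enzyme, a curated rate-limiting flag, one or more of the six KEGG
pathway categories), a product table (organism, EC, compound), an
inhibition table (organism, compound, target EC, in-vivo flag), and a 0/1
presence matrix of enzymes over an ordered reference genome panel. The
tables emulate the structure of curated resources (RLE catalogues, KEGG
LIGAND products, BRENDA inhibitors, KEGG RefSeq annotations); the package
performs no retrieval and ships no curated content.

Conventions that matter downstream:

- The RLE flag is **global**: an enzyme curated as rate-limiting anywhere
  is treated as rate-limiting in every organism that carries it. An enzyme
  belongs to every organism with an encoding gene.
- Enzymes may carry several pathway categories; per-category statistics
  count an enzyme once in each of its categories.
- Partial EC numbers (`1.1.1.-`) are accepted as opaque identifiers and
  surfaced in the validation report, since curated inhibitor data contain
  them.
- The in-vivo flag is an explicit input column; the pipeline filters to
  in-vivo annotations by default (configurable), because only naturally
  occurring intracellular inhibition is evidence of physiological
  regulation.

## Pair construction

An inhibiting pair (provider → target, mediated by compound *c*, in
organism *o*) exists iff the product table links (o, provider, c) and the
inhibition table links (o, c, target) with in_vivo true. The pair set is
exactly this compound-join, deduplicated on (provider, target, compound).
Annotations are never transferred between organisms, so organisms with
sparse inhibitor data yield sparse networks — a property of the data, not
a bug. Self-pairs (product inhibiting its own producer) occur in real
annotations; they are retained and flagged, with a switch to drop them.

All statistics count **distinct entities** — distinct inhibitor compounds,
distinct provider/target ECs — never link multiplicity, so a promiscuous
compound does not inflate coverage.

## Statistics

**Hypergeometric upper tail.** All enrichment questions reduce to
P(X ≥ k) for X hypergeometric with population N, successes K, sample n.
The tail is evaluated through scipy's log-space survival function, which
is exact (to double precision) far past N = 10⁶; the test suite checks it
against exhaustive enumeration of all C(N, n) samples for every valid
configuration with N ≤ 12, at 1e-12. p-values are reported raw — one-sided,
no multiplicity correction — so the tool reports evidence and never
decides significance for the user. The specific tests:

- *Inhibitor production*: population = distinct compounds produced in the
  organism, successes = those produced by ≥ 1 RLE, sample = produced
  compounds that are in-vivo inhibitors. Inhibitor compounds never produced
  in the organism fall outside the population and are excluded from the
  sample (they carry no information about producers).
- *RLE targets*: population = enzymes of the organism (per category when
  stratified), successes = RLEs, sample = distinct inhibited targets.
- *ADP vs AMP*: population = conserved pairs initiated by either
  nucleotide, successes = those with RLE providers, sample = the ADP side.

**Percentages** are reported to two decimals; the headline
inhibitor-production figure is additionally rounded to the nearest integer
percent, ties away from zero. Fractions with zero denominators are
reported as null, never as 0.

**Jaccard similarity.** For binary profiles A, B over the panel,
J = M₁₁/(M₀₁+M₁₀+M₁₁) counts co-presence against any presence, ignoring
joint absences (M₀₀), which for an 82-genome panel would otherwise dominate
rare enzymes. When both profiles are all-zero the score is undefined and
the pair is excluded from means (scoring it 0 would assert dissimilarity
the data cannot support); exclusions are logged and counted.

**Pair classes** are nested: *common* = all pairs, *rle_provider* = pairs
with a rate-limiting provider, *rle_both* = both members rate-limiting.
Before averaging, pairs are collapsed to distinct (provider, target) so a
pair mediated by many compounds is not over-weighted. Class means are
compared with Welch's unequal-variance t-test (Welch–Satterthwaite degrees
of freedom, scipy implementation, verified in tests against the textbook
formula at 1e-10), one-sided "greater" by default because the scientific
hypotheses are directional. Mean ordering across classes is data-dependent
and is **not** asserted as an invariant; only the planted-simulation
recovery (below) is.

**Cross-pathway pairs.** A pair is cross-pathway when provider and target
category sets are **disjoint** — the conservative choice for
multi-category enzymes; a "not identical" criterion is available. The 6×6
matrix counts, per (source, target) category cell, distinct targets
inhibited from the source category by any provider vs by RLE providers.

**Conservation.** Pair identity across organisms is (provider EC,
target EC); the mediating compound set is carried as an attribute, and a
pair is "initiated by" a compound if that compound mediates it in at least
one organism. Threshold: ≥ 3 organisms by default (minimum 2; raising the
threshold provably never enlarges the set). These identity choices are the
closest literal reading of counting "enzyme pairs" across organisms while
still supporting per-compound summaries.

## Synthetic data generator

The generator emulates the joint structure the analysis assumes, not real
KEGG/BRENDA content: EC numbers are synthetic identifiers, pathway labels
are uniform draws, and no phylogenetic tree structures the panel. A global
template of products, inhibitor annotations and targets is drawn once;
the first (anchor) organism carries every enzyme and link, and each
further organism carries each enzyme independently with probability
`p_shared_across_organisms` (0.7 by default), so a pair recurs exactly
where both members do.

Defaults (the study conditions): 5 organisms (`hsa`, `mmu`, `rno`, `sce`,
`eco` as conventional names), 400 enzymes of which 25% are flagged
rate-limiting, 350 compounds, Poisson(2) products per enzyme (truncated at
≥ 1), base inhibitor probability 0.2 with a 2× boost for RLE-produced
compounds (yielding ~60–75% RLE-produced inhibitors), Poisson(4) targets
per inhibitor drawn with 2× weight on RLEs (yielding ~40% RLE targets),
an 82-genome panel (23 + 59), presence probability 0.5 per genome, and
profile coupling `rho_pair` = 0.6.

**Profile coupling** plants the class-mean ordering: for a pair whose
provider is rate-limiting, each genome position of the target profile is
copied from the provider's base profile with probability ρ_eff, where
ρ_eff = `rho_pair` for rle_provider pairs, min(1, 1.5·`rho_pair`) for
rle_both pairs, and 0 for pairs with a common provider. When one target
enzyme appears in several template pairs, only the single strongest
coupling is applied (ties broken by provider EC), always copying from the
provider's *base* profile — this avoids order-dependent chained couplings
and keeps the generator deterministic. Copying is directional
(provider → target) but Jaccard is symmetric, so direction does not affect
scores. Because one profile is shared across all pairs touching an enzyme,
class means are diluted mixtures of coupled and uncoupled comparisons —
as in real data, where an enzyme's profile serves every pair it joins.

**Null correctness.** With `inhibitor_boost` = 1, `p_rle_target_boost` = 1
and `rho_pair` = 0, nothing in table generation depends on the RLE flags,
which are a uniform random subset of enzymes. Conditional on any realized
target (or inhibitor) set, the RLE overlap count is then exactly
hypergeometric, so the pipeline's enrichment p-values are exact null
p-values. The calibration test exploits this: over 200 null datasets the
rejection rate at 0.05 must fall in the exact binomial 99% interval
around 0.05. Discreteness of the hypergeometric makes the test mildly
conservative; the default table sizes keep the p-value grid fine enough
for the band.

**What passing tests do and do not show.** The generator plants marginal
enrichments and pairwise profile coupling, but not: realistic EC/pathway
topology, degree distributions of real metabolic networks, phylogenetic
correlation among panel genomes, or organism-specific curation biases.
Green tests therefore demonstrate that the pipeline detects the structures
it claims to detect at the stated power, and is calibrated when they are
absent — not that any specific biological dataset will show them.

## Numerical and reproducibility choices

- One seed; all randomness flows through named sub-streams spawned
  deterministically from it, so identical configurations generate
  byte-identical files (hashes recorded in a run manifest).
- Writers sort all set-valued fields; reports carry the package version
  and a configuration hash but no timestamps, so full pipeline reruns are
  byte-identical.
- Count distributions are truncated Poisson (≥ 1 where emptiness would
  break invariants) — a simplicity choice, not a claim about real degree
  distributions.
- Degenerate inputs are reported as null with a logged warning rather
  than raising: empty categories, zero-inhibitor organisms, Welch tests
  with fewer than two scores or two constant groups, ADP/AMP tables with
  an empty side.
- Simulation-based tests run at reduced problem sizes chosen for
  statistical adequacy: null calibration uses 200 single-organism datasets
  at the default table sizes; power checks use 100 replicates each
  (500 enzymes for the production-enrichment power; defaults for the
  profile-coupling recovery).

## Known limitations

- The genome panel's identities are user-supplied; the default panel is a
  placeholder with the documented 23/59 prokaryote/eukaryote split, and
  kingdom tags are currently carried but not used in any statistic.
- Conservation treats organisms symmetrically; no phylogenetic weighting.
- No inhibitor potency (Ki), flux modeling, or network-topology metrics —
  the analysis is deliberately set-theoretic and statistical.
- Cross-pathway fractions for sparse category pairs rest on very few
  targets; the tool reports the counts alongside every fraction so users
  can judge support.
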