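# rlenet

Rate-limiting enzymes (RLEs) in metabolic inhibitory networks: pair
construction, enrichment statistics, phylogenetic-profile similarity and
cross-organism conservation.

## The problem

Rate-limiting enzymes catalyze the slowest step of a metabolic pathway and
carry high flux-control coefficients, which makes them natural points where
metabolism couples to regulation. One fast regulatory channel is *product
inhibition*: a metabolite produced by one enzyme acts in vivo as an
inhibitor of another. `rlenet` analyzes this channel systematically. It is
aimed at systems biologists who want to quantify, in one organism or across
several, how strongly the curated RLE subset of the enzyme complement
dominates the inhibitory network — as the *providers* of inhibitors, as
their *targets*, and as partners in evolutionarily conserved inhibitory
relationships.

## The model

The unit of analysis is the **inhibiting enzyme pair**: an ordered pair
(provider, target) within one organism such that some compound *c* is a
metabolic product of the provider and an in-vivo inhibitor of the target.
Pairs are the compound-join of a product table (organism, EC, compound) and
an inhibition table (organism, compound, target EC, in-vivo flag);
annotations are never transferred between organisms.

On the resulting directed network the package computes:

- **Provider/target coverage** per organism and per KEGG pathway category
  (Carbohydrate, Lipid, Nucleotide, Amino acid, Cofactor and vitamin,
  Others): distinct provider and target counts, the RLE subsets, and the
  fraction of targets reachable from RLE providers.
- **Hypergeometric enrichment** (one-sided, upper tail). For a population
  of N entities containing K successes and a sample of n containing k,
  p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n). Used for: in-vivo inhibitors among
  RLE products, RLEs among inhibited targets, and the ADP-vs-AMP provider
  comparison.
- **Cross-pathway regulation**: pairs whose provider and target pathway
  annotations are disjoint, tallied into a 6×6 source-by-target category
  matrix of RLE-vs-all target coverage.
- **Phylogenetic-profile similarity.** Each enzyme gets a binary profile
  over an ordered panel of 82 reference genomes (23 prokaryotes + 59
  eukaryotes); similarity of two profiles is the Jaccard coefficient
  J = M₁₁/(M₀₁+M₁₀+M₁₁), which ignores joint absences. Pair classes are
  nested — *common* (all pairs) ⊇ *rle_provider* ⊇ *rle_both* — and class
  means are compared with one-sided Welch (unequal-variance) t-tests.
- **Conservation**: pairs recurring in ≥ 3 of the analyzed organisms, and
  the summary of conserved pairs initiated by a given compound (by default
  ADP, C00008, vs AMP, C00020) with the 2×2 hypergeometric test of whether
  RLE providers concentrate on ADP.

A fully parameterized synthetic-data generator emits all four input tables
with this structure planted at configurable strength (inhibitor-production
boost for RLEs, RLE-target weighting, profile coupling within pairs,
cross-organism sharing), so every stage of the pipeline can be tested for
calibration and power without any database access.

## Worked example

```python
import rlenet as r

config = r.GeneratorConfig(seed=1)          # default study conditions
dataset, truth = r.generate(config)
pairs = r.build_pairs(dataset.products, dataset.inhibitions,
                      dataset.enzymes, "hsa")
stats = r.inhibitor_production_stats(dataset.products, dataset.inhibitions,
                                     dataset.enzymes, "hsa")
cov = r.coverage_report(pairs, dataset.enzymes, "hsa")
print(f"pairs: {len(pairs)}")
print(f"inhibitors: {stats.n_inhibitors} ({stats.percent}% RLE-produced)")
print(f"providers: {cov.providers_all} ({cov.frac_providers_rle:.1%} RLE)")
print(f"targets: {cov.targets_all} "
      f"({cov.frac_targets_by_rle:.1%} covered by RLE products)")
enr = r.enrichment_rle_targets(pairs, dataset.enzymes, "hsa")
print(f"RLE-target enrichment: k={enr.k}, n={enr.n}, K={enr.K}, N={enr.N}, "
      f"p={enr.p_value:.3g}")
```

prints

```
pairs: 1054
inhibitors: 99 (74% RLE-produced)
providers: 191 (34.0% RLE)
targets: 242 (81.4% covered by RLE products)
RLE-target enrichment: k=80, n=242, K=100, N=400, p=1.84e-06
```

Reading: in the simulated "human" organism, 1054 inhibiting pairs were
built; 74% of its 99 distinct in-vivo inhibitors are products of RLEs; only
34% of inhibitor providers are RLEs, yet their products reach 81% of all
inhibited targets — the minority-provider / majority-coverage pattern the
analysis is designed to expose; and inhibited targets are significantly
enriched in RLEs (80 of 242 targets are RLEs vs 100 of 400 enzymes overall).

The same analysis runs from the shell:

```bash
rlenet simulate --seed 1 --out runs/demo-data
rlenet report --data runs/demo-data --out runs/demo-report
```

which writes the pair edge list, coverage and enrichment tables, the
cross-pathway matrices, profile-similarity class means and Welch
comparisons, conserved-pair and compound-initiation tables, and a single
`summary.json`.

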