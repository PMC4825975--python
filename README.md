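# oligoheart

Oligogenic variant discovery for congenital heart malformations.

Severe cardiac malformations such as the atrioventricular septal defect
(AVSD) rarely trace to a single recurrent mutation: cohorts of affected
children instead show scattered de novo and inherited variation across many
loci. `oligoheart` implements a discovery pipeline built for exactly this
situation, for statistical geneticists and genomics analysts working with
trio exome and case/control data:

1. **Trio rare-disease inheritance model** — filter variant calls on panel
   minor allele frequency (MAF ≤ 0.03), per-member read depth (≥ 8) and a
   genotype-quality score in [0, 1] (≥ 0.5), keep protein-altering
   consequences, drop blacklisted genes, and classify each proband's
   variants as *de novo* (child carries an allele absent in both parents),
   *rare homozygous* (child hom-alt, each parent a single-copy carrier) or
   *compound heterozygous in trans* (two heterozygotes in one gene, one of
   unambiguous maternal and one of unambiguous paternal origin).
2. **Developmental coexpression modules** — WGCNA-style module detection on
   a tissue expression atlas (adjacency |cor|^β, topological-overlap
   dissimilarity, average-linkage clustering), module eigengenes correlated
   to tissue-of-origin, and intersection of the heart-tissue module with
   inheritance-model genes.
3. **Heat-diffusion subnetworks** — per-gene mutation scores diffused over
   a protein-interaction network with the insulated random walk
   F = β (I − (1−β) W)⁻¹; directed exchanged-heat edges E = F·diag(h) above
   a threshold δ are kept and strongly connected components of size ≥ 2
   reported, with significance from degree-preserving network permutations
   (empirical p floored at 1/n_perm).
4. **Weighted burden replication** — per subnetwork, the SKAT linear
   weighted score test Q = (y−ŷ₀)ᵀ G W² Gᵀ (y−ŷ₀) with Beta(1, 25)-density
   MAF weights w_i = 25(1−p_i)²⁴, four genotype principal components as
   covariates, a mixture-of-χ² p-value (Liu moment matching, Imhof
   inversion fallback), and Bonferroni control (0.05/86 ≈ 5.81e-04 for the
   reference family of 86 tests).
5. **Exact and Monte-Carlo set statistics** — log-space one-tailed
   hypergeometric enrichment, Fisher's exact test on carrier tables, and
   gene-set permutation p-values p = (r+1)/(n+1).
6. **Consensus CNV filtering** — calls supported by ≥ 2 of 3 callers,
   longer than 100 kb, with trio inheritance and known-locus annotation.

A first-class synthetic-cohort generator (`oligoheart.simulate`) emits every
input with known ground truth — trio VCF/PED with planted inheritance
events, a case/control genotype matrix with planted gene-set burden, an
expression atlas with planted tissue modules, and a scale-free interactome
with a planted hot clique — so each stage is testable end to end.

## Worked example

Simulate the default discovery design (59 affected + 59 control trios,
~20k sites, planted events in 16 disease genes), run the inheritance model
and contrast carriers between cohorts:

```python
from oligoheart.simulate import CohortConfig, gene_names, simulate_trio_cohort
from oligoheart import trio, stats

cfg = CohortConfig(seed=1, planted_genes=tuple(gene_names(16))).noiseless()
cohort = simulate_trio_cohort(cfg)
calls = trio.cohort_to_calls(cohort)
events = trio.classify_inheritance(trio.filter_variants(calls), cohort.trios)
_, summary = trio.collate_by_gene(events)
print("events:", summary["n_events"], "genes:", summary["n_genes"],
      "probands:", summary["n_individuals"])

universe = sorted(set(cohort.sites["gene"]))
case_ids = cohort.trios[cohort.trios.phenotype == 2]["child"]
ctrl_ids = cohort.trios[cohort.trios.phenotype == 1]["child"]
case_inc = trio.incidence_matrix(events, case_ids, universe)
ctrl_inc = trio.incidence_matrix(events, ctrl_ids, universe)
idx = [universe.index(g) for g in gene_names(16)]
table = stats.carrier_table(case_inc, ctrl_inc, idx)
print("carrier table:", table)
print("fisher one-tailed p: %.3g" % stats.fisher_exact(table, "one_tailed"))
mc = stats.montecarlo_geneset_p(case_inc, ctrl_inc, idx, n_perm=999, seed=2)
print("monte-carlo p: %.3g  (r=%d, n=%d)" % (mc.empirical_p, mc.r, mc.n))
```

```
events: 14 genes: 9 probands: 12
carrier table: ((12, 47), (0, 59))
fisher one-tailed p: 0.000131
monte-carlo p: 0.001  (r=0, n=999)
```

The generator planted 14 qualifying events in 12 of the 59 affected
probands; all are recovered, none of the 59 control probands carries one,
the one-tailed Fisher test on the carrier table rejects at p = 1.3e-4, and
no random 16-gene draw out of 999 produces a statistic as extreme, so the
permutation p sits at its floor 1/(999+1).

The same flow is scriptable: `oligoheart run --config pipeline.yaml --out out/`
executes all three analyses from one YAML file and writes per-stage TSV/JSON
artifacts plus a manifest; the subcommands `simulate`, `inherit`,
`coexpress`, `hotnet`, `burden`, `enrich` and `cnv` expose the stages
individually.

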