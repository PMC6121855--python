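# mycocluster

Comparative-genomics machinery for discovering secondary-metabolite gene
clusters in fungal genomes and for detecting their horizontal transfer
(HGT) between mushroom lineages.

Fungal biosynthetic pathways — such as the psilocybin pathway of
hallucinogenic Agaricales — are often encoded in gene clusters: a
decarboxylase, a P450 monooxygenase, a phosphotransferase, a
methyltransferase and a transporter sitting within a few genes of each
other on one scaffold. Because a clustered pathway can move between
species in one piece, such clusters show two telltale genomic signatures:
a *phylogenetically patchy presence/absence pattern* that tracks the
phenotype rather than the species phylogeny, and *gene trees in which the
recipient nests inside the donor lineage*. `mycocluster` implements the
full inference chain that exploits both signatures, plus a
synthetic-genome simulator that plants clusters and transfer events as
ground truth so every stage can be validated end to end without any
sequence downloads.

## What it does

1. **Homolog groups** (`mycocluster.homology`) — Smith–Waterman similarity
   search (BLOSUM62, affine gaps 11/1, Karlin–Altschul e-values), a
   similarity graph with edge weight −log₁₀ e-value, and Markov Clustering
   (MCL, inflation 2.0) into homolog groups.
2. **Cluster discovery** (`mycocluster.discovery`) — retain groups present
   in **all** producer (PS+) genomes and at most one non-producer (PS−)
   genome; chain candidate genes into loci wherever two candidates are
   separated by ≤ 6 intervening genes; refine boundaries over a 10-gene
   window; confirm each locus by conserved synteny in other genomes
   (e-value ≤ 1e−5, similarity ≥ 0.40).
3. **Trees** (`mycocluster.phylo`) — Poisson-corrected distances,
   neighbor joining with column-resampling bootstrap, greedy
   majority-rule consensus species trees from single-copy families, exact
   per-site log-likelihoods under an empirical amino-acid model
   (Felsenstein pruning), and a one-sided RELL bootstrap for comparing
   topologies.
4. **HGT screen** (`mycocluster.hgt`) — the staged donor-targeted screen:
   best-hit filter → preliminary-tree topology filter (query sister to a
   donor sequence, ≥ 2 ancestral nodes before any background taxon) →
   bootstrap-tree nesting filter (> 2 nodes with > 70% support) →
   rejection of the vertical-inheritance constrained topology at p < 0.05.
5. **Reconciliation** (`mycocluster.reconcile`) — duplication–loss (LCA
   mapping) and duplication–transfer–loss (dynamic programming) event
   parsimony with costs 1.5 / 3.0 / 1.0, including support-based edge
   collapse at threshold 1.0.
6. **Genome content** (`mycocluster.content`) — genome × group count
   matrices, unit-variance PCA ordination, 95th-percentile loading
   selection, one-tailed Fisher enrichment with Bonferroni correction, and
   niche-specific group detection (≥ 3 dung / ≥ 4 wood / ≥ 2
   ectomycorrhizal genomes, absent elsewhere; dual-ecology genomes count
   for both of their niches).
7. **Simulator** (`mycocluster.simulate`) — species trees, gain/loss gene
   content, indel-free protein evolution under a BLOSUM62-derived
   reversible model, a planted 5-gene cluster in producer genomes, and
   explicit HGT events, all reproducible from one seed with a full truth
   log.

## Worked example

Simulate six genomes (three psilocybin-producer analogues scattered across
the species tree, 300 background gene families, one planted cluster
transfer between the two most distant producers) and run discovery:

```bash
cat > config.yaml <<EOF
simulate:
  n_taxa: 6
  n_background_families: 300
  seed: 11
discovery:
  max_negative: 1
EOF
mycocluster discover --config config.yaml --out-dir out --seed 11
```

which prints the staged counts and writes the loci table:

```
homology: 1506 -> 297 (7.0s)
taxon_filter: 297 -> 5 (0.0s)
colocalization: 5 -> 3 (0.0s)
boundary_refinement: 3 -> 3 (0.0s)
cross_genome_support: 3 -> 3 (0.0s)
3 cluster loci -> out
```

Reading: 1,506 proteins collapse into 297 homolog groups; 5 groups have
the producer-consistent taxon distribution; those candidates co-localize
into exactly one locus in each of the three producer genomes (G04, G05,
G06), each confirmed by cross-genome synteny. `out/loci.tsv` lists the
five member genes per locus — e.g. in G04 the cluster spans order indices
12–16 on scaffold `scf005` with the decarboxylase / monooxygenase /
methyltransferase / phosphotransferase / transporter genes contiguous, the
same five homolog groups in all three genomes. The truth log
(`out/truth.json`) confirms these are exactly the planted cluster genes.

The same config style drives the HGT screen (`mycocluster hgt-screen`),
reconciliation (`mycocluster reconcile`) and content ordination
(`mycocluster content`); see `docs/methods.md` for the model behind each
stage.

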