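# Methods

This note documents the models and procedures implemented in
`mycocluster`, the defaults they run under, the design choices that were
genuinely open, and what the simulation-based validation does and does not
establish.

## Substitution model

All sequence simulation and likelihood computation uses one fixed
reversible 20-state amino-acid model derived from BLOSUM62. BLOSUM62
entries are half-bit log-odds `B_ij = 2·log2(q_ij/(p_i p_j))`, so target
substitution frequencies are recovered as `q_ij ∝ p_i p_j 2^(B_ij/2)`
using the published BLOSUM62 background frequencies `p`. The equilibrium
frequencies are the marginals of `q`, the exchangeabilities are
`s_ij = q_ij/(π_i π_j)`, and the rate matrix `Q = S·diag(π)` is normalized
to one expected substitution per unit branch length. `P(t) = exp(Qt)` is
computed through the symmetric eigendecomposition
`D^{1/2} Q D^{-1/2}` and matches `scipy.linalg.expm` to 1e−15; the model
satisfies detailed balance exactly, so total likelihoods are invariant to
root placement (pulley principle), which the tests assert. Sites are
independent with equal rates and there are no indels: families are
natively aligned by construction, and the column-trimming step
(`trim_columns`, max gap fraction 0.5) is a documented stand-in that
becomes active only on externally supplied alignments.

## Synthetic genomes

The generator produces the statistical structure the analyses assume,
with defaults chosen once as the package's study conditions:

* **Species tree** — a birth–death topology on `n_taxa = 6` genomes,
  branch lengths rescaled to a mean root-to-tip depth of 0.45 expected
  substitutions/site (congeneric-fungus scale: orthologs at roughly
  50–75% identity) and floored at 0.02 so no two genomes are effectively
  identical.
* **Producers** — 3 taxa chosen by greedy max–min tree distance, making
  the producer phenotype phylogenetically disjunct, which is precisely
  the pattern the taxon filter exploits.
* **Gene content** — 300 background families; presence evolves by a
  two-state gain/loss Markov chain (gain 0.05, loss 0.20 per unit branch,
  root presence 0.90). The per-branch transition probabilities follow the
  standard two-state closed form, and a 2,000-family test checks
  empirical branch-change frequencies against it to 3 standard errors.
  A configurable fraction of families can instead be ecology-linked:
  present exactly in the genomes carrying one niche label.
* **Sequences** — lengths uniform on 100–180 residues; the planted
  cluster's five genes are 250 residues and evolve at 0.4× the background
  rate (biosynthetic enzymes are conserved; this also matches the high
  inter-genus similarity typical of such clusters).
* **Cluster and HGT** — five families (decarboxylase, monooxygenase,
  methyltransferase, phosphotransferase, MFS transporter) inserted
  contiguously on one scaffold per producer genome, member order shuffled
  within the locus. By default one cluster transfer connects the two most
  distant producers: the recipient's cluster sequences are evolved on a
  gene tree in which the recipient leaf is re-grafted halfway along the
  donor's terminal branch.
* **Determinism** — every stochastic draw comes from a named CRC32-keyed
  substream of one global seed; outputs are bit-reproducible.

What the simulator does **not** emulate: indels and alignment error, rate
heterogeneity across sites and lineages, paralog-rich families and tandem
duplication, assembly fragmentation and annotation error, and composition
bias. Passing tests therefore demonstrate the *inference logic* — the
filters, chaining, tree statistics and reconciliation — not robustness to
alignment or annotation noise.

## Homology

Candidate pairs must share ≥ 3 exact 4-mers (an index-based prefilter);
survivors are aligned by Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1), using Biopython's aligner. E-values come from the
Karlin–Altschul formula with fixed gapped-BLOSUM62 constants (λ = 0.267,
K = 0.041) and search space = query length × total database residues.
"Amino-acid similarity" is operationalized as the fraction of aligned
(ungapped) columns with a positive BLOSUM62 score — the retrieval tools
this stage replaces do not publish their definition, so borderline edges
may differ from theirs. The graph weights edges by −log₁₀ e-value (capped
at 200, reciprocal hits averaged); within/between-genome weight rescaling
as done by OrthoMCL is deliberately omitted — group recovery, not score
parity, is the validated property.

MCL runs per connected component on dense column-stochastic matrices with
self-loops set to the node's maximum incident weight, alternating
expansion (squaring) and inflation (entrywise power 2.0, renormalize,
prune entries < 1e−5) until the flow changes by < 1e−6 or 200 iterations
(non-convergence returns the current partition, flagged). Clusters are
read off attractor rows; a node claimed by several attractors goes to its
highest-flow attractor, ties to the lowest index. An independently
written textbook MCL (no pruning, no per-component decomposition) serves
as the reference in tests.

## Cluster discovery

Gene position is the 0-based rank along a scaffold; "n intervening genes"
counts genes strictly between two candidates; strand is ignored. The
taxon filter retains groups present in all PS+ genomes, in at most
`max_negative` PS− genomes (default 1), and in at most 4 genomes total.
Chaining is single linkage: consecutive candidates with ≤ 6 intervening
genes merge, and a reportable locus needs ≥ 2 genes from ≥ 2 distinct
groups (tandem copies of one family are not a cluster).

Boundary refinement iterates over a 10-gene window on each side: a flank
is admitted iff its group passes the same phenotype filter **and** its
group lies within the window of the corresponding locus in at least one
other cluster-bearing genome. The second condition is the package's
operationalization of "convergence of synteny": with phenotype filtering
alone, a background family that passes the taxon filter by chance and
happens to sit near the cluster in one genome would be absorbed; requiring
the flank to be reproduced near a sibling locus removes exactly those
one-genome coincidences. The same member-wise rule prunes raw loci, and a
final locus must share ≥ 2 groups with a locus in another genome. Under
the default conditions this yields exact planted-cluster recovery
(precision = recall = 1.0 across 20 seeds).

## Trees

Distances are Poisson-corrected p-distances over shared non-gap columns,
capped at p = 0.95. Neighbor joining uses the standard Q-criterion with
lexicographic tie-breaking and zero-clamped negative lengths; on exactly
additive matrices it provably recovers the generating tree, which the
tests confirm to 1e−9 in branch length. Bootstrap supports are the
percentage of column-resampled NJ replicates containing each bipartition
of the point tree. The species tree is the greedy (extended
majority-rule) consensus of bootstrap NJ trees from randomly sampled
single-copy (1:1) families whose mean internal support exceeds 70%
(quota 100 by default; tests and the acceptance script use 20–25, which
already recovers the generating topology exactly at the simulated signal
strengths). NJ + distance methods stand in for full ML tree search
throughout: the pipeline's claims are topological, and the simulated
signal regimes are ones where NJ and ML agree.

Site log-likelihoods are exact (Felsenstein pruning with per-site
rescaling; gaps are missing data). Competing topologies are compared with
a one-sided RELL bootstrap: resample site indices, count the fraction of
resamples in which the constrained tree's total log-likelihood is at
least the optimal tree's, reject below α = 0.05. Two numerical rules
matter here. First, *both* topologies get branch lengths refit to the
same distance matrix by nonnegative least squares over the path-edge
incidence system before likelihoods are computed — comparing a
data-fitted tree against a tree with independently obtained lengths is
systematically biased against the latter. Second, the type-I calibration
simulations floor internal branches at 0.08 substitutions/site: when the
generating topology is effectively unresolved, "the true tree" is not
identifiable and any best-versus-prespecified comparison is
anticonservative by construction, so calibration is only meaningful on
resolvable trees. Under these conditions the measured type-I error at
nominal 0.05 is ≈ 0.04 over 200 null simulations.

## HGT screen

Stage 1 keeps queries whose best non-self hit is from a donor taxon;
same-genome hits are excluded from the ranking (otherwise recent paralogs
would mask every donor signal). Stage 2 roots a quick NJ tree at the leaf
most distant from the query and requires (a) a donor sequence in the
query's parent clade and (b) ≥ 2 consecutive rootward ancestors that add
no background-taxon leaf; an alternative reading (internal-node distance
to the nearest background leaf) is available as `mode="distance"`.
Stage 3 repeats the test on a bootstrap tree and requires more than two
nodes with support > 70 on the chain of ancestors whose subtrees contain
only surrounding-group leaves. Trees larger than 250 leaves are first
reduced to the largest supported clade containing the query. Stage 4
builds the vertical-inheritance topology by constrained NJ — the
recipient-lineage leaves are joined first (midpoint-rooted sub-NJ) and
re-attached as a composite taxon — and rejects it by the RELL test.

The family used for tree building is the query's hit set augmented by the
hits of the query's best (donor) hit: a deeply transferred query can
legitimately fail to retrieve its own-lineage relatives at the e-value
cutoff, which would otherwise make the vertical constraint unbuildable.

The screen's error rates are measured on a fixed 10-taxon scenario
(recipient with two close relatives; a 4-taxon donor ladder; three
outgroups; 20 all-present families of 150–200 residues; transfers move 5
families from the most nested donor to the recipient). Measured:
specificity 1.0 over 200 vertical simulations (zero stage-3 candidates,
matching the expectation that a genome-wide scan of vertical data comes
up empty) and sensitivity ≈ 0.9 over 50 transfer simulations (all five
transferred genes flagged with the vertical constraint rejected); misses
are bootstrap-support dips on one of the three required chain nodes.

## Reconciliation

DL reconciliation is the classical LCA mapping (provably minimal):
duplications where a node maps to the same species node as a child,
losses from mapping-depth differences. DTL is a dynamic program over
(gene node × species node) placements with events speciation (free,
losses along each descent), duplication (1.5, losses from the node
itself) and transfer (3.0, one child moves to any species node that is
neither the current node nor one of its ancestors, loss-free on the moved
side). Transfers are not checked for global time consistency — the
standard undated-parsimony relaxation. Equal-cost ties prefer
speciation > loss > duplication > transfer, then the lexicographically
smallest species node, so event counts are deterministic. The DP is
verified against an exhaustive enumeration over all species-node
assignments on a systematic ≤ 5-leaf sweep (612 gene/species pairs) and
satisfies DTL-cost ≤ DL-cost on 1,000 random pairs (the DTL scenario
space contains DL's). Gene-tree edges with support below the edge-weight
threshold (default 1.0 on the 0–100 scale, i.e. only zero-support edges)
are collapsed first; polytomies are re-binarized by greedily joining the
child pair with the deepest species LCA.

## Genome content

Groups present in one genome or in every genome are uninformative for
ordination and dropped. Columns are zero-centered and scaled to unit
variance (constant columns dropped — unit variance is undefined);
PCA is computed by SVD with the sign convention that each loading
vector's largest-magnitude entry is positive, and is checked against an
eigendecomposition of the correlation matrix. Loading selection takes
the 95th percentile (linear interpolation between order statistics) of
the positive, and separately of the negative, loadings per component.
Enrichment is scipy's one-tailed Fisher exact test, verified against an
integer-arithmetic hypergeometric sum to 1e−12, Bonferroni-corrected by
the number of loading sets (default 4). Niche-specific detection requires
≥ 3 dung / ≥ 4 wood / ≥ 2 ectomycorrhizal genomes and zero presence
outside the niche; genomes carrying two ecology labels count toward both
of their niches and never disqualify a group for either. A qualifying
group is flagged polyphyletic when its presence set is not a clade of the
species tree. The 20-seed recovery check runs on a 16-genome scenario
(6 dung including two dual dung+wood, 8 wood, 4 mycorrhizal; 15% of 150
families ecology-linked) and compares detections against the truth log's
presence patterns.

## Problem sizes

Validation runs use deliberately moderate sizes chosen to exercise every
code path with comfortable statistical resolution: 20 discovery datasets
of 6 genomes × 300 families, 200 + 50 screen simulations of 10 genomes ×
20 families, 200 RELL null simulations of 6 taxa × 300 sites, 1,000
random reconciliation and Fisher instances, and 100-instance oracle
sweeps elsewhere. The full acceptance run completes in a few minutes on
one CPU.

## Known limitations

* No indels, alignment uncertainty, or rate heterogeneity anywhere in the
  stack; `trim_columns` is a placeholder for real alignment filtering.
* E-values use fixed Karlin–Altschul constants rather than per-pair
  estimated parameters; absolute e-values are approximate even though
  edge ranking is robust.
* The similarity definition (positive-scoring column fraction) is one of
  several reasonable readings; thresholds near 0.40–0.45 may admit or
  exclude borderline homologs differently from heuristic search tools.
* NJ replaces ML search; on short internal branches ML would resolve
  more; the RELL test approximates the multiscale-bootstrap AU test and
  is expected to be slightly liberal near polytomies.
* DTL ignores transfer time consistency, as is standard for undated
  parsimony; scenarios it reports can be undatable.
* The screen's sensitivity figure is specific to the simulated signal
  regime (strong, recent transfers into a well-sampled donor clade).
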