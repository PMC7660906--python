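# Methods

## The verticality model

The package treats vertical inheritance as the null hypothesis for each
gene in each higher-order prokaryotic taxon, under two assumptions: the
traditionally recognized taxa ("phyla") are real monophyletic groups, and
phylogenetic inference is most reliable at the tips of trees.  Reading a
gene tree only at its tips — does each taxon's set of sequences occupy one
side of a single branch? — sidesteps deep-branch inference noise entirely.
The true inter-phylum branching order has no effect on any score.

For a tree and taxon *a*, the monophyly score is S_a = n_a/N_a if *a* is
monophyletic and 0 otherwise, with n_a the number of distinct genomes of
*a* in the tree and N_a the number in the full dataset (carried by the
taxon map, overridable per taxon).  Gene verticality V_g = Σ S_a over taxa
present; it is bounded by the number of taxa present and rewards genes
that recover monophyly across a dense sampling of many taxa.  Monophyly is
decided at the *sequence* level (every copy, including in-paralogs, must
fall on one side of a split) while n_a counts genomes; a multi-copy taxon
whose copies straddle a split scores zero.

Two deliberate choices where the procedure is genuinely open:

* **Singletons count as monophyletic** (a single leaf is trivially a
  clade) and score 1/N_a.  A flag (`score_singletons=False`) zeroes them
  instead; the monophyly flag itself is unaffected.
* **Conserved clusters** are those with mean branch length over *all*
  edges (terminal and internal) ≤ 0.1 substitutions/site, boundary
  inclusive.  The direction of the inequality is stated inconsistently in
  the literature this mirrors; conserved = slowly evolving is the reading
  adopted everywhere here.

Aggregation: taxon verticality is the mean V_g over trees containing the
taxon, P_mono the fraction of those trees where it is monophyletic, and
the signed weighted mean adds V_w for trees where the taxon is
monophyletic and subtracts it where it is paraphyletic, divided by the
tree count.  Genome verticality averages V_g over the clusters containing
the genome.  Retention defaults mirror the intended data regime (≥ 4
genomes spanning ≥ 2 taxa); under-threshold clusters are flagged
`excluded` rather than dropped.

## MAD rooting

The weighted verticality V_w = M·d̄ (monophyletic-taxon count times mean
root-to-tip distance) and terminal duplication detection need a root.
Minimal Ancestor Deviation places the root at the point R minimizing the
RMS over leaf pairs of r_ij = |d_Ri − d_Rj|/d_ij, the relative deviation
of the induced ancestor (the projection of R onto the i–j path) from the
pair midpoint.  Per branch the interior optimum ρ has the closed form
ρ̂ = Σ_cross[(d_ij − 2 d_vi)/d_ij²] / (2 d_uv Σ_cross[1/d_ij²]), clamped
to [0, 1]; only cross pairs depend on ρ.  The winning branch gains a
degree-2 root node at ρ̂.

Numerical/degenerate handling:

* leaf pairs at zero path distance (identical sequences) are dropped from
  the deviation sums with a warning; an all-zero-length tree is an error;
* **ambiguity**: a tree is flagged ambiguous when the two best branch
  scores differ by less than 1e-6 relative (configurable).  Near-ties
  rather than exact ties are used because floating-point MAD scores of
  symmetric trees differ at machine precision.  Ambiguous trees are
  skipped by the duplication counter;
* rooted trees keep their degree-2 root; all unrooted analyses suppress
  degree-2 nodes internally, so re-reading a rooted Newick is safe.

## Sister analysis

For an edge-separated clade, the candidate sisters are the subtrees
adjacent at its attachment node (two in a binary tree, more at
polytomies); the one joined by the shortest branch wins, ties broken by
fewer leaves, then lexicographically smallest leaf name (the tie rules are
this package's convention — ties are measure-zero in real branch
lengths).  Sister composition is scored by relative *leaf* occurrence (so
each profile sums to 1); a paraphyletic taxon is decomposed into maximal
monophyletic subgroups whose profiles are combined weighted by the
fraction of the taxon's genomes each subgroup holds.  A recent export from
taxon A into another phylum leaves A inside its own sister profile — the
self-sister signature of tip LGT.  The cross-tree matrix is row-normalized
by each row's maximum.

In eukaryote–prokaryote (EPC) trees where the eukaryote leaves form a
split, the adjacent node bisects the prokaryotic side into subclades; the
one with the fewest leaves is taken as the sister (ties: shorter branch,
then name) and classified pure (one prokaryotic phylum) or mixed.  The
enrichment question — are the clusters with a given pure sister more
vertical than the EPC sample? — is answered with a two-sided Wilcoxon
rank-sum test of their V_g against all clusters, requiring ≥ 3 cases; the
choice of test is this package's (the underlying comparison is a location
shift between two samples of scores with heavy ties).

## Terminal duplications

A terminal duplication is a two-leaf cherry whose leaves share a genome,
counted on unambiguously MAD-rooted trees.  Larger same-genome clades
contribute only their internal cherries: the counted unit is the pair.
Group means divide total pairs by *all* genomes in the provided map
(genomes with zero pairs included) — this is the normalization under which
the published totals 32,277/5,655 and 109,056/150 reproduce the printed
5.7 and 727 duplications per genome.  The per-genome duplicated fraction
is 2·pairs/genome-size (both cherry members are duplicates); ECDFs are
computed per group, with optional repeated subsampling of larger groups to
a common size to guard against sample-size artefacts.  The
prokaryote/eukaryote contrast is reported as the plain ratio of the two
group means; no other normalization is applied.

## EPC merging and annotation

A eukaryotic cluster merges with a prokaryotic cluster when ≥ 50% of each
side's sequences (sequences without a retained hit stay in the
denominator — the conservative reading) have their best reciprocal
alignment hit in the other cluster, after filtering hits at e-value
≤ 1e-10 and local identity ≥ 30%.  "Best" per sequence is minimal
e-value, ties by higher identity, then name.  Plurality ties or
non-mutual best partners mark the pairing ambiguous; ambiguous EPCs are
discarded downstream.  The procedure is symmetric in the two cluster
tables and monotone in the thresholds.

Header annotation scores every header by the summed cluster-wide
occurrence counts of its words (lowercased, punctuation stripped,
mixed letter+digit tokens dropped as accession-like) and returns the
highest-scoring header, first-listed on ties.  Function annotation is a
majority rule over supplied per-gene labels, ties to the
lexicographically smallest, with "Poorly characterized" for unlabelled
clusters.

## RELL topology tests

KH and SH tests consume a trees × sites matrix of per-site
log-likelihoods; sites are resampled with replacement (multinomial
weights), never re-optimized.  Conventions: the KH test is one-sided (is
the candidate worse than the reference?); replicate sums are centered at
their per-tree replicate mean (the centering convention of the upstream
tools is not recoverable, so per-tree centering is fixed here and
verified by the type-I calibration test); p-values are clamped below at
1/B.  The default B = 100,000 replicates matches common practice;
calibration tests use B = 1,000, which keeps the null rejection rate
within the 99% binomial band of α = 0.05 over 1,000 simulated matrices.
`topo_test_suite` computes KH and SH on one shared set of replicate
weights, which makes SH's conservativeness (p_SH ≥ p_KH) hold replicate
by replicate.  The AU test is not re-implemented — its multiscale
bootstrap belongs to specialist software — but externally computed AU
p-values can be carried through the decision workflow.  The eukaryote
monophyly decision follows the rule: monophyly is rejected only when the
best constrained tree is significantly worse than the unconstrained one.

## The synthetic generator

`SimConfig` defaults describe, scaled down, the regime the framework
targets: 42 taxa (the dataset's taxon count) of 10 genomes each, with each
gene sampling genomes at q = 0.1 — trees of ~40 genomes, between the
median (18) and mean (~139) cluster sizes of the motivating dataset —
one expected transfer and 0.1 expected duplications per tree, and an
ultrametric species tree of within-taxon depth 0.1 substitutions/site
under a 0.2 backbone.  Tests and the acceptance script use 4–6 taxa × 4–5
genomes and 100–200 trees per condition, sizes chosen so the full suite
runs in well under a minute per module while every rate estimate has
two-digit precision.

Transfers are single-leaf prune-and-regraft moves (the recent, tip-visible
LGT the measure detects), with reattachment excluded from the original
edge so every event changes the topology; subtree transfers are out of
scope.  Duplications turn distinct leaves into same-genome cherries, so
planted counts are exactly recoverable.  Branch lengths get multiplicative
lognormal jitter (σ = 0.2, mean-one) unless disabled.

What the generator does *not* emulate: sequence-level inference error
(trees are true topologies, not estimates), gene birth–death along the
species tree, rate heterogeneity across lineages, within-taxon
non-monophyly of the species tree itself, and ancient transfers.  Passing
tests therefore demonstrate the correctness and calibration of the
statistics on known-truth trees — not robustness to phylogenetic
reconstruction artefacts in real data, which is precisely the noise the
tip-based design minimizes but cannot abolish.

## Known limitations

* Published full-dataset values (per-taxon P_mono tables, R² = 0.726 of
  the verticality–distribution correlation, the 30/475 KH rejections)
  require the 5,655-genome corpus and are out of desk-scale reach; the
  package reproduces the printed per-genome duplication means and the
  topology-count arithmetic, and validates everything else by oracle
  equivalence and planted-truth recovery.
* rRNA verticality has no estimator here (no rRNA trees are consumed).
* MAD is the only rooting offered; trees whose root it cannot place
  unambiguously are excluded from root-dependent statistics rather than
  rescued by another method.
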