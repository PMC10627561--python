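# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `polyconflict`, in the order the pipeline runs.

## Tree model and primitives

Trees are rooted node structures with uniquely labeled tips; Newick parsing
and the heavy lifting of dialect handling are delegated to dendropy, while
all algorithmics run on the package's lightweight nodes. Internal node
labels are preserved as strings (support values from upstream tree
inference). Branch-length units are contextual: coalescent units (CU) for
species trees, substitutions/site for estimated gene trees.

Clade frequencies are computed on rooted clades when both the reference and
the collection are rooted (the plastid tree is rooted via outgroups),
otherwise on unrooted bipartitions. Collection trees missing reference tips
are pruned to the shared set first; a reference clade reduced below two tips
(or with an empty complement) is skipped for that tree. Robinson–Foulds is
the symmetric difference of non-trivial bipartition sets; it is
cross-checked against dendropy in the tests.

## Synthetic-data generators

The generators define the study conditions for all downstream validation;
their defaults are fixed once and are not free dials.

**Species trees.** Forward Yule simulation (default birth rate 1/CU), with a
final exponential stretch so terminal branches are positive. Written
in-package so trees are bit-reproducible from a numpy seed.

**MSC gene trees.** One lineage per species (matching a
one-transcriptome-per-species design); within each species-tree branch of
duration t × scale, lineages coalesce at rate k(k−1)/2; the root branch is
unbounded. The `scale` factor models the smaller effective population size
of uniparental organelles (4.0 for the plastome test). Terminal branches
lacking lengths — the usual situation for coalescent-summary species trees,
whose terminal branch lengths are not identifiable — receive a configurable
default of 2.0 CU; internal branches must be supplied. Node ages follow the
tips-contemporaneous convention (tips at height 0, node age = deepest child
path), which is exact for ultrametric inputs. Calibration: the concordant
quartet frequency matches 1 − (2/3)e^(−t) across t ∈ {0, 0.5, 1, 2, 5} at
n = 10,000, and running scale s equals running scale 1 on a pre-multiplied
tree exactly (same random stream).

**Network gene trees.** The same coalescent run in continuous absolute time
over a timeline of speciation and introgression events. At an introgression
event (donor branch, recipient branch, time, γ), every lineage currently in
the recipient branch independently jumps to the donor with probability γ;
moved lineages are recorded per gene tree as ground truth. γ = 0 is
statistically indistinguishable from the plain MSC engine (chi-square test
in the suite), giving a dual-route check on both engines.

**Duplication–loss homolog trees.** A single ancestral gene enters at the
root and evolves top-down: along each branch every lineage duplicates at
rate λ and dies at rate μ (events per CU per lineage); at the optional WGD
node every lineage duplicates and the extra copy is retained with
probability r (decided at the event; losses continue afterwards). Copies are
named `species@k` and a TaxonMap is emitted. Trees losing every copy are
redrawn and counted. With λ = μ = 0 and no WGD the output is exactly the
species tree, every tree.

**Alignments.** Jukes–Cantor only: per edge of length d, a site changes with
probability (3/4)(1 − e^(−4d/3)), uniformly to another base. No rate
heterogeneity, no indels — adequate for site-pattern counting, not for
model-fit questions.

**Codon pairs.** An ancestral sequence of uniform sense codons; synonymous
and nonsynonymous substitution events are drawn as Poisson(ks_true · S) and
Poisson(ka_true · N) with NG86 site counts S, N, and placed by rejection
sampling proportional to each codon's current synonymous (resp.
nonsynonymous) site count. Multiple hits arise naturally, so the estimator's
Jukes–Cantor correction is genuinely exercised; stop codons are never
emitted. Realized event counts are returned as truth.

**Ks mixtures.** Log-normal components parameterized by their natural-scale
medians and log-scale SDs, truncated to [0.05, 3] with resampling. The
default two-component setting (medians 0.18 and 0.75, log-SD 0.25, weights
0.6/0.4, n = 3000) emulates a young WGD peak superimposed on an older one.

## Curation rules

Orthogroup selection retains an orthogroup iff it has ≥ 1 copy in every
species, mean copy number ≤ 5, and median ≤ 2. Mean/median are computed over
species with ≥ 1 copy; counting absent species as zeros is available as an
option since either reading is defensible.

Long-branch pruning iterates two rules to a fixed point, absolute cuts
first: (a) any branch > 0.5 substitutions/site is cut and the component with
more tips kept (ties keep the non-leaf side); (b) a tip whose branch is both
> 0.2 and > 10× the longest *terminal* branch in its sister clade is
removed. The sister comparison uses the maximum (the conservative reading;
mean would prune more). Trees reduced below four tips are flagged as
discarded, not raised. The procedure is idempotent (property-tested).

RT orthology roots the homolog tree on the maximal all-outgroup clade
around an outgroup copy (or that copy's own edge when the outgroups are not
monophyletic), drops the outgroups, and walks rootward-to-tipward: a node
whose child subtrees share ≥ 1 species is a putative duplication and only
the child with more distinct species survives (ties: more tips, then
lexicographically smallest species set — fully deterministic); disjoint
children are both explored. Maximal single-copy subtrees with ≥ min_taxa
species are emitted. On duplication-free inputs this returns exactly one
ortholog with the input's ingroup topology.

## Plastome ILS test

`plastome_ils_test` simulates n gene trees (default 10,000) on the nuclear
tree at the organellar scale (default 4.0) and reports, for every
non-trivial plastid clade, its frequency among the simulations, whether it
is shared with the nuclear topology, and — for unique clades — an
ILS-plausibility call. A unique clade with frequency ≤ threshold (default
0.15) is ILS-implausible: ILS cannot plausibly generate a clade that almost
never arises under the MSC, so hybridization (or error) is implicated. The
threshold mirrors a reading of results rather than a prescribed cutoff and
is exposed as a parameter. The analytic anchor: a clade conflicting with a
t-CU branch arises with probability ≤ (1/3)e^(−t), i.e. < 0.01 already at
t = 5 after scaling.

## Quartet tests

qcCFs use a canonical resolution order (labels sorted; resolutions pair the
smallest label with each of the others in turn), making every output
deterministic. A gene tree contributes to a quadruple iff it contains all
four taxa and resolves them.

Both tests fit the MSC null: counts ~ Multinomial(n; 1 − 2μ, μ, μ), μ ∈
[0, 1/3]. T3 takes the modal count as concordant, μ̂ = min((n − n₁)/(2n),
1/3); T1 fixes the concordant class from the species tree, so a discordant
modal class inflates the statistic and is rejected naturally. The LRT is
2[Σ nᵢ ln(nᵢ/n) − n₁ ln(1 − 2μ̂) − (n − n₁) ln μ̂] with 0·ln 0 = 0. The
default p-value is a parametric bootstrap (B = 2000, re-estimating μ per
replicate): the published tests use nonstandard boundary asymptotics that we
do not reproduce; the bootstrap is assumption-light and its type-I error at
α = 0.01 is verified to sit inside the exact binomial 99% band at the
study-scale n = 365. A chi-square(1) approximation is available for speed
and agrees closely away from the μ boundaries. p-values are invariant to
permuting the two minor counts (tested).

Rejected quadruples are mapped to every internal species-tree edge whose
bipartition splits the quadruple 2|2 — precisely the edges forming the
induced quartet's internal path. This attribution rule is our construction;
gene flow should concentrate counts on few edges while estimation error
spreads them.

The per-edge concordance score takes each internal edge's quadripartition
(A, B, C, D), aggregates quartet counts (q₁, q₂, q₃) with q₁ the resolution
joining A and B (exhaustive when |A||B||C||D| ≤ 2000, else a seeded sample),
and returns 1 + Σ pᵢ log₃ pᵢ, negated when the modal resolution is not the
reference: 1 = full concordance, 0 = maximal conflict, negative = a
dominant alternative. This is a documented analogue of published
quadripartition internode-certainty scores, not a byte-for-byte
reimplementation.

## D-statistics

Only gap-free, strictly biallelic four-row site configurations count;
ambiguity codes are missing data. With the outgroup allele ancestral (A)
and the alternative derived (B), ABBA ⇔ (p1, p2, p3) = (A, B, B) and BABA ⇔
(B, A, B); D = (nABBA − nBABA)/(nABBA + nBABA). The bootstrap resamples
alignment columns with replacement (the resampling unit in the source
analyses is unstated; a block option is provided and recommended for
concatenated multi-locus alignments, where single-site resampling
understates the SD because sites within a locus share a genealogy). Z =
D/SD, two-tailed normal p, Holm–Bonferroni across all combinations of a
design; significance requires both Z > 3 and adjusted p < 0.05. Designs are
summarized as "significant gene flow" (> 50% of combinations significant),
"insignificant" (< 10%), or "ambiguous" (the unnamed middle band).

## Duplication mapping

LCA reconciliation is standard: each gene node maps to the LCA of its
children's mappings; a node is a duplication iff it maps with a child;
losses follow the depth-gap rule (gap for duplication children, gap − 1 for
speciation children). It is verified exactly against an exhaustive
minimum-cost oracle on all small instances in the suite.

The ladder analysis walks from an anchor taxon to the root (optionally
restricted to one representative per subtending clade). For each gene tree
and ladder node, the *maximal* gene subtrees LCA-mapping to that node are
candidates; a candidate is examined iff it contains ≥ 1 copy of every
ladder taxon the node covers and contains no duplication mapping to any
other node (the topological-concordance filter; branch lengths are
ignored). It supports a shared duplication iff some duplication node maps
to the focal node with each child retaining ≥ 1 ingroup taxon.

Significance pools simulation replicates per node and applies one-sided
Fisher exact tests: observed above the null pool, and not below the
positive pool. A node can be flagged WGD-like only where the positive model
itself exceeds the null (at nodes the simulated WGD does not affect, the
consistency comparison is uninformative and would otherwise admit false
flags). Positive simulations should match the retention-rate regime being
tested; the suite uses matched pools per r ∈ {0.2, 0.5, 0.8}. Pooling
(rather than replicate-level rank tests) is the simple documented choice.

## MUL-tree search

`build_mul_tree` grafts a copy of the H1 clade onto the edge above H2
(H2 = H1 encodes autopolyploidy; H2 inside H1 is invalid). Reconciliation
minimizes duplications + losses over the assignment of each H1-species gene
copy to one of the two MUL leaves: exhaustive (exact) up to 12 ambiguous
tips, otherwise greedy single-tip flips from random restarts, validated
against the exact mode on small instances. `grampa_search` scores every
(H1, H2) plus the singly-labeled tree, ranking by total cost (ties: fewer
duplications, then hypothesis id) and reporting per-hypothesis counts of
gene trees reconciled strictly better than the singly-labeled baseline. On
simulated allopolyploid data the true hypothesis ranks first and beats the
singly-labeled tree; without WGD the singly-labeled tree wins — the
diagnostic contrast the method exists for.

## Ks estimation and mixtures

NG86: per-codon synonymous site fractions (changes to stop codons count as
nonsynonymous sites) averaged between the two sequences; multi-difference
codons average Sd/Nd over all minimal substitution pathways, with
stop-traversing pathways given weight zero (all-stop cases fall back to
counting those steps as nonsynonymous). Ks = −(3/4) ln(1 − (4/3) pS) and
likewise Ka; pS ≥ 3/4 is flagged undefined. Codons containing non-ACGT
characters are skipped. The implementation agrees with biopython's NG86 to
machine precision and with a hand-enumerated toy exactly.

Mixtures are fitted on log-Ks (the WGD-literature convention; the natural
scale is right-skewed), EM with k-means initialization and 10 restarts per
k via scikit-learn; BIC = −2LL + (3k − 1) ln n selects k over 1..5.
Back-transformed component means (= medians of the implied log-normals) are
reported as peaks.

The paralog/ortholog comparison restricts both tables to shared orthogroups
(controlling gene-specific rate variation), isolates each table's dominant
mixture component by posterior membership ≥ 0.95 — our reading of
isolating distributions "with 95% probability"; a credible-interval reading
is also defensible — and compares means with a Welch unpaired t-test
(no pooled-variance assumption).

## Pipeline and reproducibility

The `polyconflict` CLI exposes each stage; `run --config` chains them from a
YAML config with a versioned key schema (unknown keys are rejected by name)
and writes a manifest (file, stage, seed, parameters, sha256). All
randomness derives from one root seed expanded per stage via SHA-256, so
reruns are byte-identical for deterministic stages.

## Problem sizes and numerical choices

Validation experiments run at: 10,000 trees for simulator calibration and
the ILS test; 2000 replicates × B = 2000 bootstrap for T3 calibration; 200
data sets each for D-statistic null (20 kb alignments) and power (100 loci
× 300 bp, γ = 0.3, block bootstrap); 20 data sets × 1000 trees with pooled
20 × 1000 null/positive simulations for WGD-node recovery; 20 data sets ×
300–490 trees for MUL-tree recovery; 100 replicates × 5000 codons for
estimator consistency; n = 3000 for mixture-peak recovery. Monte-Carlo
assertions use 3 binomial standard errors; exact assertions (Holm,
reconciliation, NG86 toy) use none.

## Limitations

- JC69 only for sequence simulation; no rate heterogeneity, codon models, or
  indels — synthetic alignments are cleaner than real transcriptome data, so
  passing tests demonstrate correctness of the machinery, not robustness to
  alignment error, saturation, or model misspecification.
- One allele per species throughout; no within-species polymorphism.
- Species trees are assumed ultrametric in CU for the network simulator's
  absolute-time bookkeeping; non-ultrametric inputs get the
  tips-contemporaneous convention with dead time on short branches.
- The MAPS-style concordance filter and the rejected-quartet edge
  attribution are documented readings of procedures whose published
  descriptions leave edge cases open; they are validated against simulations
  with known truth, not against the original programs' outputs.
- The MUL-tree heuristic (beyond 12 ambiguous tips) is not guaranteed
  optimal; the exact mode is used wherever feasible.
- Gene trees are treated as known; gene-tree estimation error enters only
  through the curation filters, not as a modeled quantity.
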