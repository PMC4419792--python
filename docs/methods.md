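# Methods

## Scope and model of the problem

`copiievo` re-implements, as a reusable and fully testable pipeline, the
comparative-genomic and phylogenetic procedure used to resolve *ancient
paralogs* — gene duplicates that already coexisted in the Last Eukaryotic
Common Ancestor (LECA) — in the COPII vesicle-coat family (Sar1, Sec23,
Sec24, Sec13, Sec31, plus the accessory Sec12, Sec16 and the fungal Sed4).
Because no sequence accessions ship with the package, a gene-family
simulator provides data with known duplication/loss histories; every
downstream stage is validated against that ground truth, and the published
survey's presence/absence pattern is shipped as a text-encoded matrix for
the ancestral-content reconstruction.

The pipeline has four layers:

1. **Simulation** (`copiievo.simulate`) — a species scaffold with gene
   duplications, losses and rate heterogeneity, and a sequence-evolution
   engine.
2. **Search** (`copiievo.search`) — exact Smith–Waterman similarity search,
   Karlin–Altschul E-values, reciprocal-best-hit (RBH) orthology, a PSSM
   profile search, and a cascading query strategy.
3. **Phylogenetics** (`copiievo.phylo`) — progressive alignment, gap-based
   trimming, Poisson-corrected distances, neighbor joining (NJ), and
   nonparametric bootstrap.
4. **Inference** (`copiievo.scrollsaw`, `copiievo.reconstruct`) — the
   taxon-sampling-reduction workflow (supergroup-specific trees, supported
   clades, shortest-branch surrogates, pan-eukaryotic reassembly, ancient
   clade counting) and Dollo-parsimony reconstruction of the LECA
   complement.

## The species scaffold and what the simulator emulates

The scaffold is a rooted, approximately ultrametric species tree over five
eukaryotic supergroups (Opisthokonta, Amoebozoa, Archaeplastida, SAR/CCTH,
Excavata), with the root identified with the LECA and a *stem edge* above
the root on which pre-LECA duplications are placed. Default depths (in
expected substitutions per site at rate 1): tips are 0.5 below the LECA
(supergroup crowns at 0.25, balanced within-supergroup topology), the
backbone uses 0.05 internal edges, and the stem is 0.4 long. These depths
are free parameters of the design — the taxonomy the survey is read on has
no published branch lengths — chosen so that within-supergroup, between-
supergroup, and between-paralog divergences are clearly separated yet far
from saturation at the default 500 sites.

A `Scenario` adds:

* **duplications** at a time-fraction along a named edge (`root` = the stem);
  the fraction splits the edge for the duplicate's birth, because the
  published history orders events but assigns no times;
* **losses** as (paralog × species-subtree) blocks;
* **rate multipliers** per species subtree (optionally stem-only), which is
  how lineage-wise long branches are created. Rate variation is
  *lineage-wise only*: no per-site gamma, no paralog-specific rates. The
  artifact the workflow must survive — long-branch lineages — is a lineage
  property here.

Sequences evolve under an equal-input amino-acid model: flat
exchangeabilities with empirical background frequencies, normalized to one
expected substitution per site per unit length, exponentiated with
`scipy.linalg.expm`. Model realism (WAG/LG, gamma rates) is deliberately
out of scope: the acceptance questions are about tree/selection logic, not
model fit, and the inference side uses Poisson distances that would not
exploit a richer generator anyway. Indels are off by default so the true
site correspondence is known exactly (an optional geometric indel process
exists for aligner stress-testing only). With 20 states the maximum
expected dissimilarity is 1 − Σπ² ≈ 0.94, which bounds where distances
saturate.

Shipped scenarios (`copiievo/scenarios/`): `sec24` (three pre-LECA
paralogs, the third lost in Opisthokonta and Excavata), `sec23` (one stem
duplication, second copy lost in Excavata — hence two clades inside the
Archaeplastida), `sed4` (a young duplication inside one opisthokont
subclade), `null` (single copy). Their parameters *are* the study
conditions for the acceptance checks and are not tuned per run.

### What the simulator does not emulate

Real proteomes: there are no unrelated background proteins (so forward
search hits are always family members), no lineage-specific expansions
beyond what a scenario encodes, no alignment ambiguity without indels, no
compositional heterogeneity, and no model misspecification beyond the
Poisson-vs-equal-input mismatch. Passing tests therefore demonstrate that
the *inference logic* is correct and robust to the encoded artifacts
(long branches, losses, saturation), not that the pipeline would reproduce
any particular empirical tree.

## Search layer

`local_align` is an exact affine-gap Smith–Waterman (a gap of length k
costs `gap_open + k·gap_extend`, default −11/−1 on BLOSUM62) rather than a
heuristic seeded search: datasets are desk-scale and exactness buys
reproducibility. E-values use the Karlin–Altschul form
E = K·m·n·e^(−λS) with fixed constants per scheme (default K = 0.041,
λ = 0.267, the standard gapped BLOSUM62-11-1 values); they are not
re-estimated from data. Tie-breaking in the traceback is deterministic
(first best-scoring end cell in row-major order, diagonal-preferring
pointers).

The RBH rule is applied literally: a candidate is an ortholog of a
component iff the top hit of its reverse search against the reference
proteome is one of the expected reference sequences *and* the next-best
hit's E-value is at least 10² times larger. Two edge cases the rule leaves
open are resolved as: a singleton reverse-hit list is ruled
ortholog-if-expected and flagged `single-hit` (tiny synthetic proteomes
make singletons common), and a top hit with E = 0 passes the ratio test.
The forward search nominates candidates only (default acceptance ceiling
E ≤ 10⁻³, a documented convention, configurable); it never enters the
ratio.

The profile fallback is a PSSM, not a profile HMM: per-column log-odds in
bits with background-proportional pseudocounts, columns >50% gaps dropped,
scored by the best ungapped placement. Scores are floored at −30 bits so a
zero-pseudocount profile stays finite. The cascade retries a missing
(taxon, component) with references ordered closest-first and records which
reference succeeded.

## Phylogenetics layer

The progressive aligner builds a UPGMA guide tree on 3-mer distances
(standard word size for proteins at this scale) and merges profiles with
affine-gap global alignment; rows are pre-sorted lexicographically by id,
making the result invariant under input permutation. Trimming masks
columns whose gap fraction exceeds 0.5 (all-gap columns always go). The
0.5 default is a declared convention standing in for manual curation — no
automated threshold can reproduce hand-trimming.

Distances are Poisson-corrected p-distances with pairwise gap deletion,
d = −ln(1−p). Saturated pairs (p ≥ 0.95, or no shared sites) are set to
twice the largest finite corrected distance in the matrix, with a warning:
this keeps NJ total while pushing the unreliable pair to the tree
periphery. Note the Poisson correction underestimates multi-state
distances as d grows (at the 20-state stationary limit p ≤ 0.94); the
distance-recovery test is therefore run at shallow divergence where the
bias is far below sampling error.

NJ is the standard agglomeration with two determinism contracts: Q-matrix
ties break on the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest member id), and the Q criterion is
evaluated on the upper triangle only, because `(m−2)d − r_i − r_j` is not
exactly symmetric in floating point. Negative branch-length estimates are
clamped to zero with the deficit moved to the sister edge. Bootstrap
resamples the masked columns with replacement (default 100
pseudoreplicates) and paints each full-data bipartition's replicate
frequency onto the full-data topology — supports on one fixed topology,
not a separate consensus tree, mirroring how dual-method supports are
reported on a single figure tree in practice. A replicate whose matrix is
fully saturated counts as supporting nothing.

## Supported clades and ancient-paralog counting

A *supported clade* needs ≥2 sequences from ≥2 distinct organisms and
support meeting every threshold whose method is present on the branch
(posterior ≥ 0.8, bootstrap ≥ 50; a method absent from a tree is not
required — the internal pipeline produces bootstrap only, while externally
supplied trees may carry dual `posterior/bootstrap` labels). On unrooted
trees both sides of every internal edge are candidates, carrying that
edge's support.

Two design choices resolve ambiguities the verbal procedure leaves to
human judgment:

* **"Two shortest branches"** defaults to the path length from the clade's
  attachment point (its MRCA when the tree is rooted on the clade's edge)
  to the tip — the slowest-evolving-representative intent of
  taxon-reduction workflows — with terminal-branch-only as an option.
  Ties break lexicographically.
* **Counting clades on one tree.** Candidate sides passing the support and
  composition filters are reduced greedily to a disjoint set preferring
  larger sides, and — for ancient-paralog counting — a side may contain at
  most one sequence per organism. The per-organism cap is the mechanical
  analogue of the by-hand reasoning and iterative pruning experiments: a
  single pre-LECA paralog contributes at most one surrogate per organism,
  so a side conflating two paralog clades almost surely repeats an
  organism and is rejected, letting the per-paralog sides win. Without the
  cap, a single unrooted tree cannot distinguish one clade from the union
  of its sister clades. A counted clade must finally span ≥2 supergroups
  (configurable): with the root known only to lie among the supergroups,
  a two-supergroup span is the weakest defensible witness of pre-LECA
  presence. Leftover leaves are reported `unclassified`, never counted.

The cap means a genuine within-paralog expansion (two in-paralogs of one
organism inside one ancient clade) would split or shrink that clade; the
simulator only produces this in the young-duplication scenario, where the
behavior — the young pair surfaces as its own single-supergroup,
non-ancient clade — is the desired one. On real data with large
lineage-specific expansions the cap should be raised; that judgment is
exactly what the original manual procedure supplied.

Supergroup subsets with fewer than 4 sequences cannot support a
bootstrapped tree; subsets of 2–3 pass all their sequences through as
declared surrogates (flagged), a singleton is reported unanalyzable and
excluded.

## Dollo reconstruction

Each component's column is reconstructed under Dollo parsimony: one gain,
any number of losses. The gain sits at the MRCA of the carriers; every
maximal carrier-free subtree below it contributes one loss edge, which is
the minimum under the single-gain constraint (verified exhaustively in the
tests). `present_extra_unclassified` cells count as presence — extra
family members still witness the family. A component is in the LECA
complement iff its gain node is the root. The shipped matrix encodes the
published survey's text-stated pattern: five universal subunits, Sec12 and
Sec16 jointly absent in exactly eight named taxa, and Sed4 confined to the
Saccharomyces species and *Candida glabrata* (plus *S. cerevisiae*, where
it was first characterized); its rooted 22-taxon taxonomy ships alongside.
Copy-number questions the survey leaves equivocal (e.g. whether the LECA
carried one or two Sec23s) are reported as clade spans with supports, not
forced into the complement count.

## Numerical and determinism choices

* All randomness flows through `numpy.random.Generator`; pipeline stages
  draw seeds from the master seed via a fixed `SeedSequence.spawn` scheme,
  so any stage can be rerun in isolation and a rerun is bit-identical.
* Alignment DP kernels are numba-compiled; scores are float64 and the
  reported raw score is the rounded integer.
* Newick support labels ≤1 parse as posteriors and >1 as bootstraps unless
  a scale is declared (bootstrap proportions can legitimately be ≤1); the
  dual dialect is `posterior/bootstrap` in the node label, chosen because
  no standard exists for two supports per node.
* E-values that print positive but underflow double precision are stored
  as the smallest positive float and flagged, never as 0.

## Problem sizes used by the shipped checks

The recovery checks run 20 replicate seeds of the full pipeline at the
default study conditions (5 supergroups × 4 taxa, 500 sites, 100 bootstrap
pseudoreplicates) and report the modal count; the property suites use
200 random additive matrices (6–10 leaves) for NJ, 500 random ≤8-leaf
instances for Dollo-vs-enumeration, 100 random ≤6-mer pairs for
Smith–Waterman-vs-recursion, and 100 random trees for surrogate
minimality. The divergence-degradation grid (×1, ×2.5, ×3 on a reduced
2-taxa-per-supergroup scaffold at 300 sites) brackets the regime where
saturation erodes recovery; beyond ×3 the count statistic is chance-level
noise rather than a recovery rate.

## Known limitations

* Poisson distances and NJ stand in for mixture-model Bayesian and ML
  inference; absolute supports are not comparable to published ones, only
  the workflow logic is.
* The equal-input generator cannot create the compositional or rate-class
  artifacts that motivate site-heterogeneous models.
* The per-organism cap in clade counting trades robustness to paralog
  conflation against sensitivity to lineage-specific expansions (see
  above).
* The PSSM fallback has no gap states, so it under-scores families whose
  conservation is interrupted by indels.
* `psi`-BLAST-style iterative profile search is not implemented; the
  cascade plus PSSM path is the designated substitute and provenance
  records which reference finally succeeded.
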