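# Methods

This note records the models implemented in `chronolgt`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results well defined and
reproducible.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Dated trees and time slices

A `DatedTree` is a rooted binary ultrametric phylogeny with branch lengths
in millions of years (my).  Node ages are derived from root-to-leaf path
lengths; ultrametricity is validated with a relative tolerance of 1e-6 of
the root age (published dated trees carry printed rounding), leaf ages are
then snapped to exactly 0, and every parent must be strictly older than its
children.  Node ids are assigned in deterministic post-order so that all
downstream tie-breaking is reproducible.  Polytomies are rejected rather
than resolved: every consumer of the tree assumes binarity.

Time slices cut the tree's age span at its distinct node ages.  Within a
slice the set of living branches is constant, and two branches alive in
the same slice coexist for the whole (open) slice interval.
Contemporaneity uses open intervals: two branches that meet only at a
single node age do not overlap in time, so no zero-duration transfer can
ever be placed between them.

The spanned-subtree statistic `subtree_branch_length(taxa)` sums the
branches strictly between the taxa and their LCA, excluding the LCA's own
stem.  This makes the statistic a function of the spanned clade only —
required by the permutation test below, where random taxon sets must be
comparable regardless of where they attach to the rest of the tree.

## DTL reconciliation in ultrametric mode

Gene trees are embedded into the dated species tree by parsimony over
duplication (cost δ), transfer (τ), and loss (λ) events; speciations and
the family's origination are free.  The exact optimum is computed by
dynamic programming over (gene node u × species branch x × time slice t):

* pass to the next slice (free) or through a speciation node surviving in
  one child (one loss);
* speciation at a node ending the branch at the slice bottom (free);
* duplication on the branch within the slice (δ);
* transfer of one child lineage to any *other* branch alive in the same
  slice (τ) — the ultrametric-mode constraint;
* the transfer–loss composite (τ + λ): the lineage jumps to a
  contemporaneous branch without leaving a gene-tree node behind.  A
  single relaxation pass per slice suffices because two successive jumps
  in one slice are never cheaper than the direct jump.

A conceptual stem above the species root lets events predate the first
speciation (no transfers there — nothing else is alive).  Ties are broken
deterministically: speciation before pass/loss before duplication before
transfer, then lowest species node id; the backtracked embedding is
therefore unique and repeatable.  Transfer times are reported as the
midpoint of the hosting slice, a convention: the data constrain only the
slice, not the instant.  The count of co-optimal scenarios (slice-resolved,
so the same event set placed in different slices counts multiple times) is
available as optional metadata.

An independent oracle (`enumerate_min_cost`) formulates the same model as
a shortest-path problem: pieces (branch × slice) form a graph whose edges
are the legal lineage moves, all-pairs move costs come from Dijkstra, and
the minimum is taken over every placement of every gene-tree event.  The
test suite checks exact cost agreement with the DP on 200 random instances
(both trees up to 6 leaves, integer costs 1–5).

**Unrooted gene trees** are handled by sweeping all 2n−3 rootings and
keeping the cheapest reconciliation; when several input trees are supplied
for a family, the best-scoring one is kept (ties to input order).

**Ancestral genome sizes.** A node's size counts families with at least
one gene copy *at* that node — at leaves this equals the observed family
count of the genome, exactly; at internal nodes it counts lineages
crossing the speciation.  (Counting occupancy anywhere on a branch would
inflate leaf sizes whenever an optimal scenario routes a lineage along a
leaf branch before transferring it away.)  The selection criterion among
transfer:loss weights 10:1, 8:1, 5:1, 3:1 is the mean of
|size(parent) − size(child)| over edges; absolute values prevent gains and
losses from cancelling.  Duplication cost defaults to twice the loss cost
and is exposed in `EventCosts` — it is nearly inert in gain/loss/transfer
regimes, which have no duplication process.

## LGT rates

Acquisitions into a clade count every event whose recipient branch lies
below the clade's LCA *or on the LCA's stem* (a gene acquired by the
ancestor is inherited by all members).  Three normalizations are reported
side by side, because they answer different questions:

* clade-total, `n / t(LCA)` — events per my anywhere in the clade;
* per-node, `n / (n_branches · t(LCA))` — the headline rate;
* per-lineage-time, `n / Σ branch lengths` — the direct estimator of a
  per-lineage transfer intensity; only this one is expected to recover the
  simulator's configured rate, since branch time per branch varies widely
  on birth-process trees.

Donor classification assigns each branch the clade shared by all its
descendant leaves (mixed ancestry → "other lineage").  The within-clade
bias test builds the 2×2 recipient-clade × donor-clade table and applies
the two-sided Fisher exact test; a diagonal-heavy table means lineages
preferentially receive from their own clade.

The detectability fit regresses log(events per branch per my) on
log(branch length) by OLS; zero-event branches cannot enter a log fit and
are excluded and counted (a +0.5 pseudo-count mode is available).  On data
where most branches carry 0 or 1 events this fit is dominated by the
detection floor (rate ≥ 1/L whenever anything is detected), so experiments
about the decay mechanism use transfer intensities high enough that counts,
not zeros, carry the signal.

## Mutation rates

Counting follows the pathway convention on the bacterial genetic code
(translation table 11, via Biopython).  Per codon position, the
synonymous-site fraction is the share of the non-stop single-nucleotide
changes that preserve the amino acid, so synonymous + nonsynonymous sites
sum to exactly 3 per codon.  For a differing codon pair, all orderings of
the differing positions are enumerated, each step classified, and paths
through stop codons discarded (renormalizing over the rest); in the rare
case that every path is blocked, all paths are kept with stop-crossing
steps counted as nonsynonymous, preserving the invariant that synonymous +
nonsynonymous differences equal the nucleotide Hamming distance.  Codons
with gaps, ambiguity codes or stops in either sequence are skipped and
tallied.  Site counts are averaged over the two sequences.

The optional multiple-hit correction applies the Jukes–Cantor transform
d = −(3/4)·ln(1 − 4p/3) to pS and pN separately; it is enabled by default
and is what makes rate recovery accurate at moderate divergence (at
pS ≈ 0.3 the uncorrected proportion underestimates the rate by ~15%).
Beyond p ≥ 3/4 the transform diverges and the value is reported as
infinite — a saturation signal, not an estimate.

Clock calibration divides by 2·T·10⁶ for a pair separated by T my: both
lineages accumulate changes since the common ancestor.  Genome-wide totals
scale the sampled site counts by (total CDS length / sampled alignment
length) and multiply by the rate over one my.  Across many pairs the
median (not the mean) is reported, restricted to pairs below a divergence
cutoff (default 100 my): observed rates decline with divergence as sites
saturate, so distant pairs bias any uncut summary downward — the package's
saturation experiment shows the cutoff median landing closer to the
simulated truth than the uncut median.

## BGC families and phylogenetic restriction

Clusters are ordered domain strings of length ≥ 3 (shorter clusters are
assumed filtered upstream, mirroring standard cluster curation).
Similarity is 0.36 × Jaccard of the domain-type sets plus 0.64 × an order
term: Goodman–Kruskal gamma over the relative order of shared domain types
(first occurrences), mapped from [−1, 1] to [0, 1].  With fewer than two
shared types the order term is uninformative and falls back to the Jaccard
value.  Pairs at ≥ 0.7 form the similarity graph; Markov clustering is
pinned to expansion 2, inflation 2.0, pruning 1e-6, convergence 1e-8, cap
200 iterations, with clusters read off the converged attractor structure
and numbered by smallest member — fully deterministic.

The restriction test compares a family's spanned branch length with 1,000
uniformly drawn same-size leaf subsets.  Three p-values are reported:

* `p_value` — two-sided one-sample t-test of the null sample's mean
  against the observed value.  Its denominator is sd/√n_perm, so it is the
  only variant with the power to clear a 1e-5 cutoff from 1,000
  permutations; it answers "is the observed value at the null mean", not
  "is it a typical null draw", and is therefore anticonservative as a test
  of the family.  The `restricted` flag uses this p (below α *and*
  observed below the null mean), reflecting how a strict cutoff of 1e-5
  can be operative at all with a permutation null of this size.
* `p_z` — the observed value treated as a draw from the null (z-score,
  t distribution with n_perm − 1 df).  This one is calibrated: over 2,000
  null families its rejection rate at 0.05 is within [0.03, 0.07] in the
  test suite.
* `p_empirical` — exact two-sided percentile p, uniform by exchangeability
  regardless of the null's shape, with resolution 2/(n_perm + 1).

A family present on all taxa has a degenerate null (sd 0 up to float
noise) and is never flagged.  Interval-based source classification of BGC
genes counts a gene as recently acquired if a transfer of its family,
younger than the window (default 50 my), sits on the carrying genome's
ancestry path; a cluster is single-source when all its genes were acquired
in-window from one donor category.

## The synthetic-data generator

The generator supplies the statistical structure the analyses assume; no
published generative model exists for these processes, so all defaults are
package choices, set once to values a practitioner would call realistic
for a deep two-clade genus radiation and documented here.

* **Species trees** are pure-birth topologies rescaled so the root sits at
  `root_age` (default 380 my) and leaves at 0.  Because the analyses
  contrast two major clades, the topology is conditioned on each root
  child subtending ≥ 20% of the taxa (an unconditioned pure-birth root
  split is uniform and frequently leaves a one-genome "clade", for which
  no clock rate exists).  `clade_split_depth` (default 30 my) rescales
  each root-child subtree so its first internal split falls at least that
  far below the root.
* **Gene content.**  Families originate at the root (fraction
  `root_family_fraction`, default 0.5) or at branch points drawn
  proportional to branch length; each copy is lost at `loss_rate` per my
  (default 0.01), multiplied by `post_transfer_loss_multiplier` for
  horizontally acquired copies and their descendants — the mechanism that
  erodes old transfers and produces the negative rate-vs-branch-length
  power law.  Acquisition events arrive on each recipient lineage at
  `transfer_rate` per my (default 0.05); the donor is drawn from the
  recipient's clade with probability `within_clade_bias` (default 0.7) and
  from the opposite clade otherwise, uniformly among lineages alive at
  that instant, and the transferred family is uniform among those the
  donor carries.  Arrivals while the recipient's clade has no second
  lineage are dropped entirely (tallied), which keeps the donor-clade draw
  independent of the recipient — the property that makes the bias-0.5
  control an exact null for the Fisher test.  The simulation is a single
  chronological sweep, so every transfer's donor and recipient are alive
  at the event instant by construction; the event log records every gain,
  loss and transfer with its time, plus a detectability flag (the acquired
  copy left a surviving descendant).  Gene trees are the true copy
  genealogies with transfers as grafts and multi-copy genomes labelled
  `genome|k`.
* **Codon pairs** evolve per codon by a continuous-time chain: synonymous
  changes at `syn_rate` per synonymous site per year, nonsynonymous at
  `nonsyn_rate`, each event choosing uniformly among the corresponding
  non-stop neighbor codons (stops are unreachable).  Defaults 1.62e-8 and
  1.78e-9 give realistic deep-time divergences.  With the synonymous
  channel off, inferred paths on multi-hit codons can still contain
  fractional synonymous steps, so "no synonymous differences" holds only
  approximately (< 5% of differences in the test).
* **BGC strings.**  Each true family perturbs an archetype (length 8 from
  200 domain types) by per-domain substitution/indel at
  `domain_mutation_prob` (default 0.05).  Restricted families (default
  fraction 0.8) sit on the leaves of a random clade of 2 to n/2 taxa;
  dispersed families on a uniform random leaf set of the same size
  distribution, so the restriction test cannot key on family size.  The
  domain alphabet is deliberately large relative to cluster length: with a
  small alphabet, unrelated archetypes frequently share ≥ 3 domain types
  in concordant order, which alone pushes the similarity over the 0.7
  threshold and merges unrelated families.

Everything is driven by one integer seed through a single `numpy`
generator; matrices, logs, trees, sequences and test p-values are
byte-identical across reruns.

What the generator does **not** emulate: gene-tree estimation error (the
emitted genealogies are exact, so reconciliation failures in the tests
isolate parsimony non-identifiability, not phylogenetic noise);
homologous recombination; rate variation across sites or lineages; gene
duplication as a process; and genome assembly artifacts.  Passing tests
therefore demonstrate correctness and calibration of the methods under
their own assumptions, not robustness to real-data violations of them.

## Problem sizes and experiment designs

The validation experiments run at sizes chosen to give the statistics
stable expectations: oracle equivalence on 200 random ≤ 6-leaf instances;
transfer-rate recovery on five 20-taxon, 100-my, 1,000-family replicates
(counts pooled over seeds and compared with 3σ Poisson bounds around
rate × clade lineage time, stems excluded where arrivals cannot complete;
end-to-end reconciliation compared per clade against the true event count
within ±30%); power-law experiments at transfer intensity 1.0/lineage/my
so branch counts rather than zeros carry the signal (decay regime: loss
0.05 × multiplier 10 over three 31-taxon replicates; control: multiplier 1
with the Spearman correlation averaged over five 26-taxon replicates,
since a single 50-branch correlation has ±0.14 sampling noise of its own);
mutation-clock recovery on 50,000 codons at T = 10 my within ±10%;
restriction calibration on 2,000 null families (sizes 2–25, shared
per-size null samples) on a 50-taxon tree; and cost-selection behavior on
a transfer-rich 15-taxon, 150-family simulation, where the mean
genome-size change decreases monotonically from the 10:1 to the 3:1
candidate and the 3:1 weights are selected.

## Known limitations

* Parsimony reconciliation reports one optimal scenario; the optimum set
  can be large and the chosen representative is a tie-break artifact.
  Event *counts* are much more stable than event placements.
* Transfer times are slice midpoints; slice resolution equals the gap
  between adjacent node ages, which can be coarse near the root.
* The per-node LGT rate normalization divides by branch count × ancestor
  age, which over-weights short branches; cross-study comparisons should
  use the per-lineage-time rate.
* The pathway codon counting has no transition/transversion or codon-usage
  weighting; at divergences far beyond the saturation cutoff its corrected
  distances are unreliable (and flagged infinite once p ≥ 3/4).
* MCL on a thresholded similarity graph cannot split families joined by a
  chain of above-threshold links (single-linkage leakage); the in-test
  generator avoids this regime by construction, real domain data may not.
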