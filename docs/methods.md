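# Methods

This note documents the models, parameter choices and numerical behavior
of `syntrace`: family delimitation over a similarity network, gene
neighborhood (microsynteny) scoring, sub-lineage partitioning with
duplication-timing scenarios, distance phylogenetics, and the genome
evolution simulator that provides ground truth for all of it.

## Similarity network and family delimitation

The pairwise hit table (blast outfmt-6 dialect, optional 13th `ppos`
column) is symmetrized into an undirected graph: each unordered gene pair
keeps the hit with the smallest e-value.  Keeping the *best* of the two
directed hits is deliberately permissive — traversal aims to gather
homolog candidates; pruning happens later.  E-values of exactly 0 are
floored at 1e-180 so that log-scale threshold grids are well defined; the
floor is recorded on the network.

A family is the connected component containing a seed gene after removing
edges above a threshold.  Component reachability (rather than a
fixed-depth frontier) is assumed: one qualifying path is enough for
membership.  The sweep grid defaults to e-value exponents −200…−20 in
steps of 2.

**Plateau rule.**  Published analyses of this kind choose the working
threshold "by inspection" of the sweep curve; `select_threshold` makes the
inspection explicit.  A run starting at grid point *i* extends while
counts stay within `tol_frac` (default 0.01) of the count at *i*; among
runs of at least `stability_steps` (default 5) grid points the longest
wins, ties toward stringency, and the run's *opening* threshold is
returned.  The rationale: a plateau means the family boundary is
insensitive to the threshold, and its stringent end is the safest point
on it.  A curve that never stabilizes raises an explicit "no plateau"
error instead of guessing — the caller must choose manually
(`threshold_override` in the pipeline config).  Note that the longest-run
rule is evaluated on the grid actually supplied: appending permissive
grid points that extend a *later* plateau can in principle re-select it,
so the grid should end before thresholds that are biologically
meaningless for proteins (the default stops at 1e-20).

**Suspect flagging.**  Fragments (truncated gene models, frameshifts) are
flagged when protein length < `len_frac` (default 0.5) × the median
member length.  Long-branch candidates are flagged when their mean
pairwise identity distance to the other members exceeds the member median
by more than 3×MAD.  Both constants are package choices, not published
values.  Fragment and manually excluded members are dropped from pairwise
synteny scoring (but kept in all reports); `long_branch` is advisory
only, because the most divergent member of a family is often a legitimate
basal lineage — and is in fact the preferred outgroup for rooting — so
excluding it automatically would be wrong.  The analysis set is exposed as
`FamilyResult.analysis_members()`.

## Neighborhood synteny

Blocks of `k = 15` neighbors on each side of each family gene (a 30-gene
chromosome block) are extracted in ordinal gene-rank coordinates; strand
never affects membership, and contig ends are recorded.  Neighbors are
clustered at a conservative E-50 threshold; pairs of family genes scoring
zero whose blocks both contain unclustered neighbors are rescored with
E-40 clustering and marked as corroboration-level (`evidence_level:
E-40`) evidence.

Matching is one-to-one per shared cluster, greedy by ascending offset
sum, so near-query conservation is credited first and a single large
cluster cannot claim more matches than the smaller block holds.  A gene
that appears in both blocks (two family loci close together on one
contig) matches itself and counts with full similarity weight.  The two
query genes themselves never count.

The per-match weight multiplies the three evidence sources —
`w_dist = ((k−o_a+1)+(k−o_b+1))/2k`, `w_sim` = identity fraction,
`w_clu = 1/(1+log10(cluster size))` — because each source is a stated
direction of confidence and a product is monotone in each while staying
within (0, 1].  No published formula exists for combining them; this
form and the strong/weak cut at `strong_min = 5` matched pairs are
package choices and are configurable.  Large neighbor families (the
aldose-epimerase-type clusters that flank many loci) therefore still
match, but contribute little weight per pair — mirroring the argument
that a single shared neighbor from a large cluster is not convincing
synteny evidence.

## Sub-lineages, presence and duplication scenarios

Sub-lineages are connected components of family genes over synteny edges
with category ≥ weak; isolated genes are labeled singletons, and members
within `max_gap = 3` positions on one contig are labeled tandem pairs.
Copy counts per species and sub-lineage collapse multiple strains of one
species by maximum (presence/absence reasoning is species-level).

For a candidate duplication branch, the implied losses are reported two
ways because both figure in the underlying argument: the number of
descendant species lacking the copy (the "it would imply loss in five
species" form), and the Dollo-parsimony minimum — the number of maximal
all-absent subtrees below the branch, which is the smallest set of loss
branches explaining the pattern when the gene can be gained once and
never regained.  `event_total = 1 + dollo_losses` ranks scenarios;
candidates are every branch from the WGD branch down to the carriers'
MRCA, ties toward the more recent branch (a later duplication is the more
conservative claim at equal cost).  A branch under which no species
carries the copy is a degenerate scenario and raises.

The maximal-absent-subtree count is provably minimal: each all-absent
maximal subtree must contain at least one loss, and placing the loss at
its root explains it entirely.  The test suite verifies this against
exhaustive minimization over loss-branch subsets on 500 random trees.

## Distance phylogenetics

Distances are uncorrected identity distances `1 − identity/100` from the
best pairwise hit (a Poisson correction `−ln(1−p)` is available but off
by default — downstream logic uses topology, not absolute lengths).
Member pairs with no direct hit get the maximal observed distance plus
0.05, logged.  Neighbor joining uses the Saitou–Nei Q-criterion with ties
broken toward the lexicographically smallest pair; negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
which preserves cherry path lengths and leaves additive matrices
recovered exactly (verified to 1e-9 on all fixture trees up to 8 leaves,
and cross-checked against scikit-bio's implementation).  Trees are
rooted on the pendant edge of the leaf with the greatest mean distance to
the rest — the most divergent sequence — with lexicographic tie-breaks.
Bootstrap supports resample alignment columns with replacement (`B`
replicates, seeded), rebuild NJ trees from p-distances, and score each
reference bipartition by its replicate frequency; supports require an
alignment, since a hit table has no columns to resample.  Bayesian and
maximum-likelihood inference are out of scope; study-grade trees can be
supplied as Newick wherever a tree is consumed.

## The simulator

`synthetic_data.simulate` evolves an ancestral genome (3 contigs × 30
random 120-residue proteins by default) down a 12-species tree shaped
like the Saccharomycetaceae: three pre-WGD outgroups and a post-WGD clade
containing Nakaseomyces-, Naumovozyma-, Kazachstania- and
Saccharomyces-like lineages, with the WGD branch marked.  Per branch, in
order: WGD (contig doubling with fresh gene uids), planted events, random
per-gene events (tandem duplication 0.005, dispersed duplication 1e-4,
loss 0.01, translocation 5e-5 per gene per branch), per-contig local
order shuffles (probability 0.02, window 4), then substitutions under a
uniform-rate 20-state Jukes–Cantor process scaled by branch length
(expected substitutions per site ≈ 0.25 root-to-leaf within the post-WGD
clade, ≈ 0.55 across the family — leaf-to-leaf identities of roughly
55–95%, matching the within-family range where E-40…E-150 thresholds
discriminate).

**Movement rates are scaled to the miniature genome.**  What creates
false synteny is a moved gene landing inside a specific 30-gene
neighborhood.  In a ~5,500-gene yeast genome that probability per event
is ~0.5%; in a ~200-gene simulated genome it is ~15%.  Using realistic
*per-gene* movement rates would therefore overstate per-locus noise
roughly 30-fold, so the dispersed-duplication and translocation defaults
are set ~30× below realistic per-gene rates to keep the per-locus
perturbation probability — the quantity that matters for synteny — in the
realistic range.  Tandem duplications and losses act locally and are not
scaled down.

**Planted histories.**  For parameter-recovery experiments a dispersed
duplication of the family founder can be planted on a named branch and
the loss of its WGD ohnolog on a deeper branch.  The planted copy lands
near the end of a contig of different ancestry — the subtelomeric-style
relocation seen in real family histories — guaranteeing its neighborhood
shares no clusters with the source locus.  In planted mode the focal
family is exempt from background loss and translocation so that the
planted events *are* the family's event history exactly; background
events still perturb every other gene and hence the neighborhoods.  Every
event is logged with full placement detail, and an independent replay of
the log must reproduce the leaf gene arrangements exactly (tested).

**True hit table.**  Hits are emitted from known homology: genes sharing
an ancestral root gene are compared column-wise (identity = fraction of
equal residues; similarity additionally counts BLOSUM62-positive pairs),
and the e-value is the fixed monotone map `exponent = −180 × identity
fraction`, no hit below 25% identity.  Identity 100% thus maps to the
network's e-value floor and ~28% to E-50.  This bypasses alignment
heuristics entirely — the simulator tests threshold logic, not aligners.
An in-package Smith–Waterman path (`compute_hits`, Biopython's
PairwiseAligner with BLOSUM62, gap open 11 / extend 1, Karlin–Altschul
e-values over the query × total-residue search space with gapped
constants λ=0.267, K=0.041) exists for small real inputs; externally
computed tabular hits are the primary path.

**What the simulator does not emulate** — indels and fragments (proteins
stay full-length, so fragment flagging is exercised only by unit
fixtures), rate heterogeneity across sites and lineages, codon-level
evolution, gene orientation changes, unequal contig sizes, and
assembly artifacts.  Passing recovery tests therefore show that the
inference chain is correct under clean locus histories with realistic
divergence and background rearrangement noise; they do not show
robustness to annotation error, which real analyses handle through the
fragment flags and manual exclusion lists.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
12-species genome sets of ~2,000 genes, 50-replicate recovery
experiments, 100-network traversal oracles, 500 Dollo oracle patterns,
NJ fixtures to 8 leaves.  A planted-history replicate (simulate → hits →
traversal → synteny → scenario ranking) takes ~2 s on one CPU.  All
randomness flows from explicit integer seeds (numpy `default_rng` in the
simulator, `random.Random` in test fixture generators); reruns of the
pipeline on the same config produce byte-identical summary JSON.
Recovery is imperfect by design — roughly 1 in 20 replicates draws a
background rearrangement near a family locus that merges the two
sub-lineages or, more rarely, leaves the duplicate branch ambiguous —
and the acceptance bar (≥ 45/50 on both measures) reflects that expected
noise floor rather than a tuned target.

## Known limitations

* Synteny categories count matched pairs only; a single shared neighbor
  pair (category weak) connects sub-lineages regardless of its weight,
  so one ancient rearrangement can merge two sub-lineages.  The edge
  weights and evidence levels carry the information needed to audit such
  merges in the reports.
* Orthology is synteny-first: cross-checks against tree topology are
  reported (lateral-transfer warnings for cross-genus identity above the
  within-genus distribution) but never resolved automatically.
* The plateau rule assumes the sweep curve has a plateau; families whose
  similarity to interlopers varies smoothly need a manual threshold.
* Dollo counting conditions on presence at the duplication branch; it
  cannot see compensating regains (horizontal transfer back into a lost
  lineage would be misread as retention).
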