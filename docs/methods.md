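# Methods

This note documents the models behind each stage, the conventions chosen
where more than one was defensible, and what the synthetic generator
does and does not emulate.

## Study design being modeled

A fully mapped forest plot (all stems with coordinates and species).  A
subset of tree species are *focal*: one stem per species is fogged with
insecticide and the fallen Lepidoptera larvae collected on a sheet spread
under the crown.  The observation method records the focal tree as each
larva's host.  The molecular method amplifies three plant barcodes
(*rbcLa*, *trnL*, ITS2) from gut contents and matches them against a
local reference library covering every plant species of the plot; some
gut contents come from *nontree* taxa (bamboos, lianas, bryophytes,
parasitic plants) that have no local reference sequences and no mapped
stems.

## Sequence processing

**QC rule.** A sequence is kept when its ungapped length is at least 80%
of the marker's expected amplicon length (inclusive boundary).  Expected
lengths: *rbcLa* 540 bp, *trnL* 500 bp, ITS2 350 bp (the lower bound of
its amplicon range, so the 80% rule is well defined), COI 658 bp
(configurable).

**Distance.** Uncorrected p-distance with pairwise deletion: positions
with a gap or N in either sequence are excluded; the distance is
mismatches over compared sites.  No model correction is applied — at the
2% barcoding threshold the correction is negligible and the uncorrected
distance is the convention the threshold was calibrated on.  Inputs must
be pre-aligned (or equal-length by construction); multiple alignment is
out of scope.

**OTU delimitation.** Agglomerative clustering cut at 2% divergence.
Average linkage is the default (single and complete are available); ties
are resolved deterministically and OTU ids are numbered by the
lexicographically smallest member, so output is independent of input
order.  The implementation delegates to `scipy.cluster.hierarchy`; the
test suite checks it against an independent exhaustive merge-scan oracle
on all random matrices up to 8 sequences.

**Taxonomy assignment.** Hits are ranked by identity, then alignment
length, then label.  A best hit outside the target insect order discards
the OTU.  If morphology is absent or agrees with the best hit's family,
the best hit's label is used; otherwise the highest-ranked of the top
five hits in the morphological family; if none matches, the OTU is
discarded as a family-level conflict (its morphological family is kept
on the record).

## Diet identification

Per marker, the candidate set is every reference taxon at maximal
identity (pairwise-deletion identity over the full query); below a
configurable floor (default 0.95) the marker is treated as unidentified.
Markers are combined in the fixed order *rbcLa*, *trnL*, ITS2: a
candidate set that intersects an existing diet item narrows the item to
the intersection; a disjoint set opens a new item.  Disjoint sets are
read as multiple true food plants, not as errors — larvae can eat more
than one plant — and are flagged in the output for audit.  A diet item's
level is species (singleton), genus (members congeneric), or family.

**Resolution scores.** At a given level an item scores 1 when it names a
single taxon at that level, 0 when ambiguous, and ½ at species level for
nontree taxa, which lack local references but are distinguishable from
every local plant sequence.  Summary means are taken over diet
individuals (a plant eaten by ten larvae counts ten times), per marker
and for the combination.

## Webs and overlap

Both webs are larva-level count matrices over the *matched* larvae (those
with a non-empty diet call).  Species complexes are single plant columns;
at genus level a within-genus complex merges into its genus column.  For
overlap bookkeeping a complex matches an observation species when that
species is one of its members — the complex is the molecular method's
best statement of the same node.  Link overlap is computed both over all
plant nodes and restricted to plant nodes present in both webs.
Percentages are rounded half-up to one decimal, matching table
conventions.

## Mismatch attribution

Decision order per diet item: (1) the item contains the collection
species at the tested level → match; (2) the item is a nontree taxon →
nontree (observation bias: the method cannot see these diets); (3) the
item is species-ambiguous: if any member species has a stem within 2 m
of the collection stem → near neighbor (observation bias), otherwise →
low resolution (molecular bias); (4) an unambiguous non-matching
species → near neighbor if its nearest stem is ≤ 2 m, far neighbor
otherwise.  The 2 m radius is the fogging sheet's half-width and the
boundary is inclusive.  Distances are stem-to-stem Euclidean (no crown
geometry — crown data are generally unavailable).  A larva with several
items takes the most favorable category in the order match > near > far >
nontree > low resolution.  Method contributions are computed over
mismatched larvae only: observation = near + far + nontree, molecular =
low resolution.

**Confirmation counts** (`accuracy_by_level`) use a stricter rule than
the match category: confirmation at a level requires the candidate set to
name a *single* taxon at that level equal to the host's, so a congeneric
complex containing the host confirms the genus but not the species.
This makes family ≥ genus ≥ species counts structural.  The match
category, by contrast, uses containment, because a complex containing
the host is evidence for feeding on it, not against.

## Detection logistic

One record per classified larva: y = 1 iff its category is match, x =
the number of larvae of the same insect species collected on the same
host species across the whole data set (records are per larva, not per
unique pair, and years/visits are pooled).  The fit is maximum-likelihood
logistic regression (statsmodels, IRLS) with Wald p-values; single-class
outcomes and complete separation raise.  Body size is available as an
alternative covariate for the no-effect check.

## Network metrics

All metrics need a web of at least 2×2 with positive total; anything
smaller yields NaN.

- **H2′** standardizes the Shannon entropy of interaction proportions
  between its extremes under fixed integer marginal totals:
  H2′ = (H2max − H2)/(H2max − H2min).  Extremes are exact (full
  enumeration of integer matrices with the observed marginals) for webs
  below 5×5 whose enumeration stays under 50,000 tables, and greedy
  otherwise: H2min by repeatedly pairing the largest remaining row and
  column totals; H2max by flooring the independence surface r·c/N and
  assigning leftover units to the cells furthest below their continuous
  target (row-major ties).  Both bounds are clamped so the observed web
  cannot escape [0, 1].  When the marginals admit a single entropy
  (permutation matrices), every feasible web is maximally specialized
  and H2′ = 1 by convention.
- **Interaction evenness** is H/ln(R·C) by default; the realized-links
  denominator H/ln(L) is available as a switch, since sources differ on
  which "Shannon's evenness" denominator to use.
- **Generality/vulnerability**: qualitative = mean partner count on the
  binary web; quantitative = marginal-weighted mean of exp(row or column
  entropy), the effective partner number.
- **NODF/WNODF**: rows and columns are first sorted by decreasing
  marginal totals (ties by original index), making the value
  permutation-invariant.  Binary pairs contribute paired overlap only
  under strictly decreasing fill; weighted pairs require strictly
  decreasing marginal totals and count cells with 0 < a_jk < a_ik.
- **Barber modularity (LPAwb+-style)**: weighted label propagation in
  which each node greedily adopts the opposite side's best-scoring
  module (a fresh singleton label is the fallback), alternated with a
  refinement stage that tries module merges *followed by re-propagation*
  (a merge with non-positive immediate gain can unlock better moves) and
  module dissolutions (splitting one module into singletons, then
  re-propagating).  Ten restarts by default: odd restarts start from
  random partitions, even restarts perturb the best partition found so
  far (30% of labels randomized).  Seeded and reproducible; the test
  suite verifies the search attains the exhaustive-partition maximum on
  1,200 random small webs.  Merge/dissolve acceptance threshold is
  ΔQ > 1e−12.

## Null comparison

"Equal number of nodes" is implemented as separately matched insect and
plant node counts, because bipartite metrics depend on both dimensions.
Subwebs are induced submatrices of uniformly drawn row and column
subsets; draws with an all-zero row or column are rejected and redrawn
(cap 10,000 attempts), keeping node counts exact rather than silently
shrinking the web.  CIs are percentile (2.5/97.5) rather than normal —
metric distributions are skewed at small sizes.  Significance flags are
plain outside-CI comparisons.  Rare-link pruning zeroes cells with count
≤ 2 and then drops emptied nodes.

## Synthetic generator

The generator plants exactly the mechanisms the analysis is meant to
recover, with defaults mirroring the sampling design:

- 1000 × 500 m plot (50 ha); 30 tree species of which 20 are fogged
  focal species; 8 nontree taxa; stems placed by a homogeneous Poisson
  process (~150 per species; a Thomas cluster process is available) —
  Poisson is the default because its nearest-neighbor distance has the
  closed form 1/(2√λ) used as a generator check.
- one fogged stem per focal species, preferring stems with a
  heterospecific neighbor inside the 2 m sheet radius so that the "near
  neighbor" mechanism is realizable at every fogged tree;
- 800 larvae across 40 insect species; insect abundances and per-tree
  herbivore loads are Dirichlet-distributed; each insect species has a
  geometric host breadth over the focal species (the per-tree larva
  count distribution is a knob, not a fixed law);
- hidden diet class per larva: focal 0.60, near 0.10, far 0.20, nontree
  0.10.  The class is drawn first and the diet taxon sampled conditional
  on it (near = a heterospecific species with a stem ≤ 2 m), so the
  planted four-way proportions hold by construction rather than only in
  expectation under rejection;
- marker amplification is independent Bernoulli per marker (rbcLa 0.30,
  trnL 0.20, ITS2 0.10, so about half of larvae yield at least one
  marker), and 10% of amplified sequences are truncated to 70% length,
  failing the QC rule — this separates "amplified" from "identified";
- sequences are i.i.d.-substitution mutants of random ancestors
  (genus-level ancestors for plants), intraspecific divergence 0.004,
  interspecific 0.05 — well separated relative to the 2% OTU threshold;
  no indels or rate heterogeneity.  With probability 0.25 a tree species
  with a congener shares its chloroplast sequences with that congener,
  and half of those pairs also share ITS2 (a full species complex);
  this plants the resolution limits and gives ITS2 the highest species
  resolution.

What the generator does **not** emulate: phylogenetically realistic
sequence evolution, indels/chimeras, PCR artifacts, seasonal phenology,
crown geometry, body-size–detectability coupling, or any dependence of
the diet class on insect identity.  Consequently, passing end-to-end
tests demonstrates that the pipeline recovers planted mechanisms under
clean conditions — not that it is robust to alignment error or marker
bias in real data.  One deliberate consequence: because the hidden diet
class is independent of pair co-occurrence frequency, the pipeline's
detection logistic has no planted slope on synthetic data; slope
*recovery* is therefore tested by simulating directly from the logistic
model instead.

## Problem sizes and determinism

Default analysis sizes were chosen so a full run stays interactive on a
laptop: 800 larvae, 500–1,000 null draws, 4–10 modularity restarts; the
test suite uses a smaller 12-species community for per-module checks and
the full default community for end-to-end ones.  All randomness descends
from a single root seed via numpy `default_rng` seed sequences (community
= [seed, 0], larvae = [seed, 1], sequences = [seed, 2], metric/null
streams derived similarly), so identical configurations give
byte-identical outputs, including serialized JSON envelopes.

## Known limitations

- The H2′ greedy extremes are heuristics for webs at or above 5×5; they
  bound but need not equal the true integer extremes (the exact
  enumeration below 5×5 exists precisely to keep the small-web values
  oracle-exact).
- Label propagation is a heuristic maximizer; on webs far larger than
  those validated against exhaustive search, the reported Q is a lower
  bound on the optimum.
- The null model is subsampling only; degree-preserving shuffles
  (Patefield-style) are deliberately out of scope.
- Empty-intersection marker conflicts are resolved by the union rule
  (multiple diet items); alternative adjudications (e.g. trusting the
  higher-resolution marker) are not implemented.
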