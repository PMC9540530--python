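# Methods

## Status categories and the set algebra

Faunal change per region is encoded as exactly one status category per
(species, region) pair:

| category | at 8000 BP | in 2020 | loss set | gain set |
|---|---|---|---|---|
| NATIVE_PERSISTING  | ✓ | ✓ |   |   |
| NATIVE_EXTIRPATED  | ✓ |   | ✓ |   |
| NATIVE_REGAINED    | ✓ | ✓ | ✓ | ✓ |
| NATIVE_COLONIST    |   | ✓ |   | ✓ |
| INTRODUCED         |   | ✓ |   | ✓ |
| FUTURE_POTENTIAL   |   |   |   |   |

The table forces the exact identity (BP8000 \ losses) ∪ gains = Y2020,
which the decomposition below relies on. A regained species is counted
as both a loss and a gain; that double-counting is what makes the
loss and gain panels sum to the net panel.

The mid-century snapshot uses a per-record `recent` flag (change event
in or after 1945) rather than calendar dates, because the analysis only
dichotomizes change at that year. A regained species is present at 1945
under either flag value: if its record is pre-1945 both the loss and the
regain had already happened; if recent, the loss itself had not yet
occurred. The flag is a single bit per record, so a species lost before
1945 and regained after cannot be distinguished from one whose entire
loss–regain cycle was recent; both resolve to "present at 1945".

One structural limitation: because categories are mutually exclusive, a
species that was extirpated from a region *and* is a candidate for
future reintroduction there cannot hold both labels. `FUTURE_POTENTIAL`
is reserved for species absent from the region's historical and current
assemblages; the synthetic generator assigns it accordingly. Future
gains are therefore measured relative to the 2020 assemblage only, not
tied back to the region's own extirpation history.

A future candidate that is globally extinct must carry
`surrogate_available` (a living relative or domestic descendant assumed
to carry the ancestor's traits and phylogenetic position); otherwise the
record is rejected, since nothing could be reintroduced.

## Subgroups

`large_nonvolant` is strictly above 2 kg and `small_nonvolant` at or
below 2 kg, so the two subgroups partition the non-volant species; a
species of exactly 2 kg is small. In a subgroup run the scaling
denominators are recomputed over the subgroup universe: pool size for
richness, the spanning subtree of the subgroup for PD, and the subgroup
hull for FRic, so the complete subgroup still scores 1 on every metric.
For the full pool the PD denominator is the total branch length of each
tree (identical to the spanning subtree when the root edge has zero
length).

## Phylogenetic diversity

Faith's PD of a tip set is the branch-length sum of the minimum spanning
subtree, rooted at the tips' most recent common ancestor
(root-excluded); one tip scores 0. An `include_root=True` variant
extends the subtree to the tree root. Root-excluded PD is monotone under
adding tips but *not* subadditive over arbitrary unions (two disjoint
cherries omit the spine joining them); the root-included variant is
subadditive, and the tests check each form where it actually holds.

PD over a tree ensemble is rescaled per tree — each tree's PD divided by
that tree's total branch length — and then averaged, reporting the
across-tree standard deviation. Rescaling per tree keeps the statistic
invariant to uniform rescaling of any one tree's branch lengths;
averaging raw PD and dividing by the mean total length (also exposed,
`per_tree=False`) does not have this property and is not the default.
A root edge, if present in the Newick, counts toward total branch length
but can never be inside a root-excluded spanning subtree; with a
zero-length root edge the full tip set scores exactly 1.

Implementation: trees are parsed with dendropy and re-encoded as parent
arrays plus a tip-by-branch incidence matrix, so PD for a tip set is one
integer mat-vec: a branch is in the root-excluded spanning subtree iff
the count of selected tips below it is at least 1 and less than the
selection size. This makes ensemble evaluation over many regions cheap.

## Trait space

Pairwise species dissimilarity is Gower's coefficient over mixed types:
continuous variables contribute |xi − xj| / range, categorical and
binary variables a 0/1 mismatch, combined as a weighted mean. Weights
equalize trait *groups* — body mass, diet, foraging stratum, activity,
habitat each carry total weight 1 split equally within the group (1/7
per diet variable, 1/3 per activity flag, 1/h per habitat flag). Body
mass enters as log10(mass in g), since mass spans several orders of
magnitude and range-normalizing the raw scale would let the largest
species dominate; this is configurable (`log_mass=False`). Range
division is the standardization for continuous variables — an
additional z-scoring would be redundant under it. Missing values are
dropped pairwise with weight renormalization; a variable constant
across the pool has no range and is dropped with a logged warning.

Gower matrices are generally non-Euclidean. An elementwise square root
is applied before ordination; no Cailliez or Lingoes correction is used.
Principal coordinates analysis double-centers −½·J·D²·J and
eigendecomposes; the top k = 5 axes are retained by default (k is a
parameter; the analysis is not expected to be sensitive to it within
reason). The embedding is refused when fewer than k eigenvalues are
positive, or when the most negative eigenvalue exceeds 5% of the
largest — the error message points at the square-root transform.
Smaller negative eigenvalues are ignored; `variance_represented` is the
retained share of the positive eigenvalue mass. Axis orientation is
fixed deterministically (first non-negligible loading positive) so runs
are byte-reproducible.

## Functional richness and overlap

FRic of an assemblage is the k-volume of the convex hull of its species
coordinates (Qhull via scipy). A hull is undefined — reported as
missing, never as zero — when the assemblage has at most k species or
the points are affinely degenerate (rank check on the centered
coordinates, tolerance 1e-9 relative). No general-position jitter is
applied to volumes, keeping them deterministic.

Occupancy overlap between two assemblages is vol(H_A ∩ H_B)/vol(H_A),
computed exactly: the facet inequalities of both hulls are pooled and
deduplicated, an interior point of the intersection is found as the
Chebyshev center (largest inscribed ball, one linear program), and the
halfspace-intersection polytope's hull volume is taken. An infeasible
LP or an inscribed radius at numerical zero means an empty or
measure-zero intersection: overlap 0. When Qhull's halfspace dual still
fails on near-degenerate inputs (it can, when the two hulls share many
vertices), the computation retries with Qhull's deterministic joggle
(`QJ`) — a numerical fallback for the intersection only; plain volumes
never use it.

## Change decomposition

With S0 the baseline set, L/G the loss/gain sets, Sp = S0 \ L and
S1 = Sp ∪ G: loss = D(Sp) − D(S0), gain = D(S1) − D(Sp),
net = loss + gain (the intermediate D(Sp) is evaluated once, so the
identity holds to machine precision). Losses are applied before gains;
the reverse order would change the two panel values for PD and FRic
(though not the net), and the chosen order follows the narrative
sequence of extirpations preceding recoveries and introductions. For
richness the decomposition is computed directly from signed set
cardinalities over the pool size, making it exact integer arithmetic up
to one division. A FRic decomposition is missing whenever any of the
three sets has an undefined hull. In summaries, a region counts as "no
change" when |net| < 1e-9 for the continuous metrics and net == 0
exactly for richness; medians and ranges are rounded only at report
time.

## Synthetic data

The generator produces the study conditions the analysis assumes, at
the scale of the European mammal fauna: a pool of 228 species, 45
regions of which 40% are islands, and a 100-tree ensemble by default
(1000-tree runs are the full-scale setting; 100 keeps routine runs in
seconds without changing the ensemble-mean logic).

* **Trees** — Yule (pure-birth) process: exponential waiting times with
  rate proportional to the number of open lineages, uniformly chosen
  splitter, a final exponential hold so every tip reaches the present;
  ultrametric by construction, no root edge. Dating realism is
  irrelevant to the metric algebra being exercised.
* **Traits** — log10 mass ~ Normal(2.0, 1.1) (median 100 g spanning
  roughly five orders of magnitude); bats (~8% of species) drawn
  lighter (Normal(1.0, 0.3)) and foraging aerially; diet a
  Dirichlet(0.5) composition × 100 rounded to integers by largest
  remainder; categorical stratum, Bernoulli activity (at least one flag
  forced) and habitat flags. Twelve species are flagged globally
  extinct, five of them with surrogates, mirroring the continent-wide
  bookkeeping of the fixture.
* **Statuses** — islands draw ~25 natives, continental regions ~120
  (islands depauperate); per-native extirpation probability 0.12 on
  islands vs 0.05 on the mainland, introductions Poisson with mean 12
  vs 6. Globally extinct species are always extirpated where native and
  never appear in any 2020 assemblage; future candidates are drawn from
  species absent from the region (skipping extinct species without
  surrogates). Era flags are Bernoulli(0.5). These contrasts produce
  the depauperate-start pattern (low-diversity regions gaining most)
  as an emergent property, not by construction.

What the generator does *not* emulate: real biogeography (range
polygons, spatial autocorrelation, shared faunas among neighboring
regions), trait–phylogeny covariance (traits are drawn independently of
the tree), taxonomically structured extirpation risk, or source-database
disagreement. Passing tests therefore demonstrate the correctness of
the accounting and the metric computations under realistic sizes and
contrasts — not that any particular empirical pattern in the real fauna
would be recovered.

The deterministic continental fixture is a single-region dataset wired
to the continent-wide bookkeeping: 198 natives at the baseline (171
persisting, 10 regained, 17 extirpated of which 12 globally extinct),
30 introductions, 211 species in 2020, 228 in total.

## Problem sizes and numerical choices

Routine test runs use 8–60 species, 10 trees and 8 regions; the
full-scale seeded run behind the summary statistics uses the default 45
regions × 228 species × 100 trees, which completes in a few minutes on
one CPU (the exact hull intersections in 5-D dominate). Monte-Carlo
oracles in the tests use 10^6 rejection samples, giving ~0.3% relative
error against the 2% assertion bands. Ties, ranks and correlations use
scipy.stats; Spearman and Pearson correlations among metric levels and
among net changes are reported per region pair with at least three
complete observations.
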