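# Methods

`pterodiv` implements the quantitative backbone of a Late Cretaceous
pterosaur diversity-dynamics analysis as a reusable, tested pipeline. This
note records the models, the conventions, and the places where a genuine
design choice had to be made.

## Ages, bins and stratigraphic conventions

All ages are in Ma before present; **larger = older** everywhere. Time
bins are contiguous half-open intervals `[t, t − w)` descending in age,
older edge inclusive, so every instant belongs to exactly one bin and a
point occurrence (fad = lad) falls in the bin whose older edge equals it.
The default bin width is 1 Ma.

Stage boundaries ship for the Late Cretaceous on the GTS2012 timescale
(`diversity_curves.STAGE_BOUNDARIES`). From these, the Santonian+Campanian
bin spans 86.3 − 72.1 = 14.2 Ma and the Maastrichtian 72.1 − 66.0 =
6.1 Ma — the unequal bins whose time-averaging asymmetry biases disparity
comparisons *against* the Maastrichtian, which is why a Maastrichtian
disparity at or above the Santonian-Campanian value is informative.

Occurrence tables store a per-taxon `[fad, lad]` range and an optional
`override_fad` applied before any computation. The override implements the
curation rule for taxa whose own record is unconstrained and which borrow
the earliest occurrence of a close relative (e.g. a dsungaripterid known
only from "Early Cretaceous" taking its relative's first appearance).
Counting is range-through: a taxon is present for the entire length of its
possible occurrence, so the fad used for calibration is the oldest bound.

## Time calibration and ghost lineages

Calibration is the minimal ("basic") scaling standard in vertebrate
palaeontology: post-order, `age(leaf) = fad`, `age(node) =
max(age(child) + min_branch)`. `min_branch` defaults to 0 (minimum
divergence dates — the convention for diversity counting) and 1 Ma is the
usual choice for plotting, where zero-length branches are illegible. The
offset is applied per child at every divergence, including chains of
nested divergences; polytomies are calibrated as-is. With `min_branch = 0`
the calibration provably minimises total ghost-lineage length for a fixed
topology (tested against brute force over discretised age assignments).

A ghost lineage is the gap between an edge's subtending divergence and the
earliest observation on that edge: for a leaf, `[parent_age, fad]`; an
internal edge is never directly observed, so any positive-length internal
edge is entirely ghost. Zero-length segments are omitted.

## Diversity curves

Taxic diversity per bin counts taxa whose range intersects the bin.
Phylogenetic diversity counts **lineage extents**: each non-root edge
contributes the interval from its subtending divergence down to its last
appearance (lad for leaves, child node age for internal edges). Counting
extents rather than "observed ranges + ghost segments" avoids
double-counting a taxon in the bin that contains its fad boundary, while
remaining a superset of the observed ranges, so `phylogenetic ≥ taxic`
holds bin-wise by construction. Internal edges of zero duration
(calibrated polytomies) carry no extent. In bins younger than every
divergence the two curves coincide — the Signor-Lipps signature of a
terminal extinction, where no younger relatives exist to imply ghost
lineages.

One caveat discovered during design: a refined grid max-pooled back to the
coarse grid does *not* generally reproduce coarse counts (two taxa can
occupy disjoint halves of one coarse bin); the coarse count is an upper
bound on the pooled refinement, with equality when ranges are long
relative to the bins. The tests assert the true direction.

## Functional morphospace

The functional matrix mixes categorical characters (habitat: continental /
brackish / marine; jaw curvature; cervical and hindlimb elongation
grades), and continuous ones (wingspan in m, ulna:humerus and
metacarpal IV:humerus ratios), with missing cells. A YAML schema is the
single source of truth for each character's kind and, for ordered
characters, its state order.

**Gower dissimilarity**: `d(i,j) = Σ_k w_ijk δ_ijk / Σ_k w_ijk`, `w = 1`
iff both taxa are observed for the character; `δ = |x_i − x_j| / R_k` for
continuous and ordered characters (ordered coded as equally spaced ranks)
and a 0/1 mismatch for categorical. Ranges `R_k` are pooled over the whole
matrix — both time bins share one geometry, which is what comparing bins
inside one ordination requires. Zero-range characters are dropped with a
warning; a pair of taxa sharing no observed character is an error rather
than an imputation. Wingspan enters untransformed by default (a log
option exists but is off: nothing in the study design requires it).

**PCoA**: eigendecomposition of `B = −½ J D² J`. Axes with eigenvalue
below `1e-10 × λ_max` are discarded. Gower matrices need not be Euclidean;
negative eigenvalues are dropped by default — matching the common default
of desktop palaeontology packages — and percent variance is computed over
the positive spectrum. A Lingoes correction is available
(`correction="lingoes"`) but off by default.

**Disparity** per group is the sum of per-axis score ranges (total spread)
and the product of ranges (bounding-box volume proxy). Both default to
*all* retained axes: published analyses rarely state a cutoff, and using
every positive axis is the parameter-free choice. Because that convention
is genuinely ambiguous in the literature, `scan_axis_subsets` recomputes
both metrics under every leading-axes choice so a published value can be
matched to the convention that produced it. Both metrics are monotone
under adding members, which is also why time-averaging (pooling sub-bins)
can only inflate them.

The isometric scaling utility `(L_a/L_b)³` converts a linear-dimension
ratio into a mass ratio under isometry; 165 mm vs 93 mm humeri give 5.58×,
i.e. ~560% to two significant figures.

## Rarefaction

`rarefy` draws subsets without replacement (default 5,000 replicates per
level), evaluates the metric on the **full-data ordination scores** of the
subset, and reports the mean and the 2.5/97.5 percentiles. Re-using the
full ordination keeps every replicate, and both time bins, in one shared
geometry; per-replicate re-ordination is deliberately not the default.
The 95% band is the simple percentile interval. Levels from 1 are
accepted (a single point has zero range; the curve's floor), and at level
= group size the band collapses onto the full-group value. The RNG is a
single seeded `numpy` Generator; the seed is part of the output.

## Parsimony scoring and search

Tree length is computed per character by exact dynamic programming over a
candidate state set (the Sankoff recursion), which handles polytomies,
polymorphic cells and missing data uniformly and exactly:

* unordered: 0/1 cost over the observed states (Fitch counts emerge as the
  special case);
* ordered: `|a − b|` over the observed integer states; a polymorphic cell
  admits its interval of states;
* continuous: characters are first rescaled to unit range
  (`(x − min)/(max − min)` over observed values — the "rescaled to unity"
  convention), then scored with `|a − b|` over the grid of observed
  values. This grid is exact: with absolute-difference costs the objective
  is piecewise linear in each internal value with breakpoints only at leaf
  values, so an optimal assignment exists on the grid.

Missing (`?`) and inapplicable (`-`) both constrain nothing (reductive
coding); the distinction is preserved at parse time for reporting only.
Length is invariant to re-rooting.

For the ensemble indices, `m_i` is the minimum conceivable steps on any
tree (smallest state set hitting every cell, computed exactly; interval
overlap for ordered/continuous) and `g_i` the star-tree cost (best single
central state or value). `CI = Σm/Σs` over all variable characters and
`RI = (Σg − Σs)/(Σg − Σm)` excluding characters with `g = m`; an
informative-only variant is a flag. For continuous characters no printed
convention exists for `m` and `g`; the rescaled range and the
star-tree (median) cost are used and documented here.

The heuristic search is deliberately modest: random-addition starting
trees (each taxon stepwise-inserted at the best edge), SPR swapping to a
local optimum, an optional parsimony-ratchet cycle (a random quarter of
characters upweighted ×3, re-swap, restore, re-swap), zero-length branches
collapsed in the reported trees (an edge is collapsed when its removal
leaves the exact tree length unchanged), and all distinct equally best
topologies retained. Determinism is guaranteed per seed. Exhaustive
enumeration (`exhaustive_search`) is feasible to ~8 taxa and is the
yardstick the search is audited against.

## Synthetic data

The generator emulates the statistical structure of the study inputs so
the whole pipeline runs with no downloads. Defaults, chosen once as
palaeontologically reasonable for a Late Cretaceous marine-pterosaur-like
assemblage:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 30 | assemblage size |
| `span` | (86.3, 66.0) Ma | Santonian through Maastrichtian |
| `extinction_rate` | 0.5 /Ma | exponential range durations, mean 2 Ma |
| `brownian_sigma2` | 0.02 /Ma | log-scale trait variance per Ma |
| `transition_rate` | 0.05 /Ma | CTMC jump rate for discrete traits |
| `missing_fraction` | 0.1 | Bernoulli missingness |
| `min_branch` | 1 Ma | calibration offset for trait branch lengths |

First appearances are uniform over the span; durations exponential (mean
`1/extinction_rate`); bin labels follow the range midpoint. Topology is
stepwise random attachment in order of decreasing fad, so older taxa
attach deeper; the tree is then calibrated with the package's own rule and
traits evolve on the calibrated branch durations — continuous traits by
Brownian motion (exponentiated, so wingspans around a 3 m root value and
limb ratios stay positive; at the default rate the spread is roughly
e^±1, matching the ~1.5–11 m span of known pterosaurs), categorical traits
by a continuous-time Markov chain simulated by Poisson jump counts. The
functional characters carry the exact seven-character study schema so the
package's own readers are exercised verbatim. A `trait_seed` separate from
the main seed allows paired designs: same occurrences and topology,
independent trait draws.

What the generator does **not** emulate: fossilisation/sampling processes
(no Poisson horizon sampling), biogeography, correlated trait evolution,
or clade-dependent missingness. Tests passing on synthetic data therefore
demonstrate the correctness and sensitivity of the *pipeline*, not the
robustness of any empirical conclusion to those real-data complications.

## Numerical choices and degenerate inputs

* Bin membership and range intersection use exact comparisons on the
  half-open convention; ties go to the older bin.
* PCoA eigenvalue tolerance `1e-10 × λ_max`; an all-nonpositive spectrum
  is an error.
* Parsimony score ties are compared at `1e-9`; equally best trees are
  deduplicated by their unrooted bipartition sets.
* Zero-range continuous characters are dropped (warning) in both Gower
  and parsimony rescaling; a character with a single observed state is
  scored as invariant.
* Empty member sets, reversed ranges, duplicate taxa, taxon mismatches
  between tree and table, and levels exceeding group size are all errors,
  not silent fixes.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
generator defaults (30 taxa), audit the parsimony search against
exhaustive enumeration at 7 taxa (945 rooted topologies), use brute-force
oracles at 5–7 taxa, and rarefy with 5,000 (curves) to 50,000 (oracle
comparisons) replicates — sizes at which every oracle is exact or its
Monte-Carlo error is quantifiable, and a full run completes in well under
a minute.

## Known limitations

* The heuristic search implements SPR only (no TBR) and a basic ratchet;
  it is an auditing tool for small-to-moderate matrices, not a TNT
  replacement. Ambiguity-aware branch support is out of scope.
* Continuous-character CI/RI conventions are not standardised across
  software; values for matrices with continuous characters are comparable
  within this package, not necessarily across programs.
* Stochastic time-scaling (cal3 and kin), tip-dating, and node-age
  confidence intervals are out of scope; calibration is minimal scaling.
* Sampling-standardised richness (SQS), origination/extinction rates, and
  Chao-style extrapolation are out of scope.
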