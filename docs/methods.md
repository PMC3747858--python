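# Methods

## The model

PFClust is a partitional, parameter-free clustering algorithm that operates
on a single input: an `n × n` symmetric matrix of pairwise similarities
`s(i, j)` with unit diagonal. Its central statistic is the **mean
intra-cluster similarity** of a cluster `C` with `m ≥ 2` members,

    E[X] = (1 / C(m, 2)) · Σ_{i<j ∈ C} s(i, j),

the mean over all unordered member pairs, self-similarities excluded. The
algorithm treats a cluster as acceptable when its E[X] exceeds a threshold
`T`, and it estimates plausible values of `T` from the data itself rather
than asking the user for one — hence "parameter-free".

### Stage 1 — randomized threshold estimation

Exhaustive search over all clusterings is impossible (their number is the
Bell number `B(n)`, provided as `bell_number` for illustration), so the
reference distribution of E[X] is built by sampling. Each of `N = 1000`
randomizations draws a cluster count `k` uniformly from `{1..n}`, assigns
every element independently and uniformly to one of the `k` slots, and
records one value per resulting cluster: E[X] for clusters of two or more
members, and 0 for singleton clusters, which have no member pairs. The
pooled values over all randomizations form the reference distribution.

The singleton zeros matter. They anchor the bulk of the distribution at
low values, so that its upper percentiles fall in the transition region
between "random mixture" and "coherent group" — precisely where useful
thresholds live. Excluding them shifts every extracted percentile into the
extreme tail of near-duplicate pairs, and no candidate threshold ever
drops below the coherence of a true group (see *Limitations*).

Twenty candidate thresholds are taken from the top 5% of the pooled
distribution: the nearest-rank percentiles {95.00, 97.50, 99.00, 99.14,
99.29, 99.43, 99.57, 99.71, 99.86, 100.00} plus the second- to
eleventh-highest pooled values. Nearest-rank (no interpolation) keeps every
threshold equal to an actually observed E[X], consistent with the
rank-based second ten.

### Stages 1A/1B — clustering at a threshold

For each candidate `T` the matrix is clustered agglomeratively:

1. **Seed**: the most similar unclustered pair forms a new cluster,
   provided its similarity strictly exceeds `T`; otherwise everything
   still unclustered becomes a singleton and the stage ends.
2. **Grow**: repeatedly take the unclustered element with the highest
   average similarity to the current members and admit it iff that average
   is at least `P·T` (default `P = 0.85`) **and** the grown cluster keeps
   `E[X] > T`. The `P·T` gate bounds the intra-cluster variance: in a very
   tight cluster an outlier could otherwise ride in on the strength of the
   other members' coherence.
3. **Refine** (single pass, ascending element index, moves visible to
   later points): every member of a multi-member cluster whose average
   similarity to its own co-members is below `T` is reassigned to the
   cluster with the maximal average similarity — even when that maximum is
   itself below `T`. A cluster drained to one member demotes it to a
   singleton. Singletons are not re-homed, and only multi-member clusters
   are candidate destinations: leftovers failed every admission gate, and
   pairing them up post hoc would create clusters no gate ever validated.

Ties anywhere (seed pair, growth candidate, refinement destination, Dunn
medoid) resolve to the lowest element or cluster index, making every stage
deterministic given the matrix and `T`.

### Selection, convergence, and the supervised mode

Each candidate clustering is scored by the mean **Silhouette width** with
dissimilarity `1 − s`; each singleton contributes exactly −1, so
over-fragmenting is penalized. The **Dunn index** (minimum inter-medoid
distance over maximum mean member-to-medoid distance, singletons excluded)
breaks Silhouette ties, and a larger threshold breaks residual ties. A
degenerate single-cluster clustering is scored 0 (neutral) with a warning
rather than failing, so selection always completes.

Because the thresholds are sampled, one run can miss the best clustering.
Four independent runs are kept; if the mean Rand index over all six run
pairs reaches 0.99 the best-Silhouette run is returned, otherwise the
oldest run with the (equal-)lowest Silhouette is replaced by a fresh run.
With an empirical per-run success probability of 0.76, four runs reduce
the chance of missing the best clustering to `(1 − 0.76)⁴ ≈ 0.3%`. A
`max_runs` guard (default 100) returns the best-so-far result with a
warning instead of looping forever; the original procedure has no
termination guarantee.

The **supervised mode** removes the randomization cost for large data: the
full procedure runs on a training subset, the three thresholds whose
candidate clusterings scored the highest Silhouette widths are each
expanded to `{(1−e)T, T, (1+e)T}` with `e = 0.05` (the source of the nine
applied thresholds is not specified beyond "selected to allow for some
variation"; a symmetric ±5% multiplicative bracket is this package's
choice, exposed as `expansion`), and the full matrix is clustered at those
nine values directly.

## Similarities from points

2-D (or d-D) point sets are converted with
`s(i, j) = 1 − ‖x_i − x_j‖` after translating the centroid to the origin
and scaling so the farthest point sits at distance 1. Centering first
makes the similarity translation-invariant; whether the original
convention centered is not stated, and the choice shifts absolute
threshold values but not the algorithm's structure. Off-diagonal values
may be negative (distances reach 2 on the unit disc); the algorithm is
defined for any real-valued similarities and negatives are kept.

## The synthetic benchmark generator

`pfclust.synthetic` regenerates the statistical structure of the standard
validation designs: circular (isotropic) 2-D Gaussian groups with gold
labels, presets `p300` (2 × 150), `p450` (3 × 150), `p1500` (10 × 150),
`p3000` (20 × 150), `p5000` (15 groups with varied spread and some
elongated groups), and `density` (20 groups of 100 subsampled to fractions
drawn in [0.05, 0.95]). Centres are rejection-sampled with pairwise
separation at least `separation · max(σ)`; the default `separation = 10`
gives clearly separated groups ("no significant overlap") while keeping a
realistic spread of boundary points. The exact σ and centre layouts of the
original datasets are unpublished, so point-for-point reproduction is out
of scope; what the generator reproduces is group count, group size, the
Gaussian radial profile, and the separation regime.

What passing tests on these data do **not** show: performance on
overlapping groups, non-convex shapes beyond mild elongation, or
non-Euclidean similarity structure (e.g. protein-domain similarity
matrices, which this package consumes but cannot regenerate).

## Numerical and design choices

- Matrix symmetry tolerance `1e-9`; accepted matrices are symmetrized as
  `(S + Sᵀ)/2` and the diagonal is set to 1.
- Gate boundaries: seed and E[X] gates are strict (`> T`), the member gate
  is inclusive (`≥ P·T`). The boundary behaviour is untestable from the
  published description; these choices mirror the pseudocode's
  inequalities.
- `b(i)` in the Silhouette includes singleton clusters as neighbours;
  nothing in the definition excludes them.
- Dunn sentinels: fewer than two multi-member clusters → `−inf` (compares
  worst in tie-breaks); all clusters internally identical → `+inf`.
- Refinement is a single pass, not a fixpoint iteration; the pseudocode
  prescribes one sweep.
- Run-level reproducibility: the convergence driver spawns one child
  generator per run from a master `SeedSequence`, so a given seed yields a
  bit-identical run sequence.
- Problem sizes in the test suite are scaled to the structure being
  tested: the cluster-count check runs the full 1500-point design, the
  recovery-rate suite uses 10 groups of 30 points over 20 trials, and the
  supervised/unsupervised comparison uses 10 groups of 50.

## Limitations

- **Few-group datasets.** The 20 thresholds come from the top 5% of the
  pooled E[X] distribution. With `g` roughly equal groups, pure
  within-group pairs make up about `1/g` of the random small clusters, and
  roughly half of those exceed a group's own E[X]. For `g ≲ 8` this tail
  mass exceeds 5%, so *every* candidate threshold lies above the coherence
  of the loosest true group and Stage 1A necessarily splits it into a core
  plus satellites. On regenerated 2- and 3-group designs the procedure
  therefore returns fragmented groups (Rand ≈ 0.7–0.97 against the
  generating labels depending on where the 95th percentile lands relative
  to the per-group E[X] values), while designs with 10 or more groups are
  recovered exactly. This is a structural property of the percentile grid,
  invariant to scale and separation; it cannot be tuned away without
  changing the published grid.
- Exactly block-constant matrices are a degenerate corner: the pooled
  maximum equals the within-block constant and the strict seed gate can
  admit nothing at that threshold (floating-point averaging usually, but
  not provably, breaks the tie downward).
- The randomization is the dominant cost, `O(N · n²)`; the supervised mode
  is the intended route for `n` beyond a few thousand.
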