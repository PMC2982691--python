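# Methods

## Model

A conditional co-regulated protein complex under condition `c` is a
connected subgraph `L = (P′, E′)` of the PPI network such that

1. every member protein's coding gene is a target of one shared TF that is
   active under `c`;
2. `L` is connected;
3. the standardized coherence `Score(L)` exceeds a threshold `α`, and the
   *pattern* of high/low score across conditions agrees with the TF's
   active/inactive pattern in at least `θ` conditions.

Requirement (iii) is the substantive one: coherence that tracks TF
activity is what distinguishes a condition-dependent co-regulated complex
from a constitutive one (high everywhere) or a spurious one (high where
the TF is off).

### Coherence and standardization

Edge coherence is the Pearson correlation between the two coding genes'
profiles, computed over pairwise-complete time points.  Time points
missing in either profile are skipped; profiles are never imputed.  Fewer
than three complete pairs, or a constant retained profile, yield an
explicit *undefined* signal (distinct from 0).  The correlation is used
signed and unweighted — deliberately without any per-gene variance
weight, because a gene can be biologically active with low expression
variance, and high variance with mediocre correlation should not inflate
an edge.

`T(L)` is the plain sum of edge coherences.  If any member gene has no
profile under the condition, `T(L) = 0` with a no-coverage flag, and the
standardized score is reported as 0.0 rather than `(0 − μ)/σ`; such
conditions count as "low score" in the consistency test, which is the
desired reading of "the data does not cover this complex here".

The null for a candidate with `K` edges is built by sampling `n` random
connected `K`-edge subgraphs of the (coverage-filtered) PPI network:
a uniform random start edge, then repeated uniform choices among the
current frontier edges.  `Score(L) = (T − mean)/std` over that sample.
Degenerate nulls (zero spread, e.g. a PPI that admits only one `K`-edge
subgraph) raise rather than divide.  Two properties of this design are
worth knowing:

* *Connectedness of the null.*  Candidates are connected, so an
  unconstrained edge-set null would be mis-centred (disconnected edge
  sets share no genes and decorrelate).  An `--null edge-set` switch
  exists for comparison.
* *Degree bias.*  Frontier growth is uniform over frontier edges, not
  uniform over all connected `K`-edge subgraphs; on non-regular graphs
  high-degree neighbourhoods are over-sampled.  On regular graphs (used
  as test fixtures) the two coincide exactly, which is how the sampler is
  validated against exhaustive enumeration.  The std of the empirical
  null also grows slightly faster than `√K` because adjacent edges share
  a gene and their coherences co-vary; this is a property of the null
  population itself, not a sampling artifact.

References are cached per (condition, `K`) with seeds derived
deterministically from the run seed, and can be persisted to TSV keyed by
a PPI content hash.

### Seed search

For each TF active somewhere, the PPI subgraph induced by its targets is
split into connected components ("WCCs" in the field's vocabulary;
the PPI graph is undirected, so weak connectivity is just connectivity).
Isolated targets are dropped — with the minimum edge count `λ = 2` they
can never enter a candidate.

Candidate enumeration inside a WCC is exhaustive canonical edge growth:
each connected edge subset is rooted at its minimum edge index and
extended only with higher-indexed frontier edges, with skipped edges
forbidden in the whole subtree, so every subset is produced exactly once.
Exhaustive enumeration is infeasible for the largest WCCs (hundreds of
edges), so a work budget (default 2×10⁶ expansions) triggers a fallback
beam search over partial subgraphs ranked by their best raw coherence
across conditions (beam width 5 000).  The beam is not exhaustive and its
use is logged.

Selection keeps candidates with best `Score ≥ α = 1.90` and activity
consistency in ≥ `θ = 2` conditions, then collapses near-duplicates:
greedily by descending score, a candidate is kept only if it shares
< 80 % of proteins with every kept one.  The overlap denominator is the
*smaller* node set (a subset counts as full overlap); `max` and `jaccard`
denominators are available.  Ties on score break to the
lexicographically smallest node list, making selection deterministic.
A candidate's ranking score is its maximum `Score` across conditions.

### Extension and regulation inference

Each seed (by default only seeds whose consistency is perfect in *all*
conditions, the high-precision subset; `extend="all"` overrides) is
extended per active condition by simulated annealing:

* a uniform random vertex `v` of the current graph, then a uniform random
  PPI edge incident to `v`;
* if the edge is present, delete it — only when the graph stays connected
  and the edge is not a protected seed edge (otherwise the proposal is a
  null move); a deletion that strands a vertex removes the vertex;
* if absent, add it (possibly introducing a new vertex);
* accept improving moves always, worsening moves with probability
  `exp(Δ/T_i)`, where `Δ` is the change in standardized `Score` (the
  edge-count-dependent reference is rebuilt lazily for each new `K`).

The temperature schedule is geometric,
`T_i = t_start · (t_end/t_start)^(i/N)` — the standard choice matching a
start/end parameterization, fast early cooling, slow late.  The default
schedule starts *near* the end temperature (`t_start = 0.05`,
`t_end = 0.01`): seeds enter the extension already locally optimal, and a
hot start mainly floods them with weak members faster than the cooled
phase can shed them (deletions are rare events under the vertex-then-edge
proposal).  `t_start` is a parameter; raise it to escape local optima.

Extensions under several conditions are intersected: only proteins added
under *every* active condition are kept, and the result graph is the seed
plus PPI-induced edges over seed ∪ intersection.  Every kept protein
whose coding gene is not already a known target of the seed's TF yields a
predicted regulation edge; per-condition attribution lists the conditions
whose individual extension contained the protein.

## Synthetic study conditions

The generator emulates yeast-style inputs at desk scale.  Defaults:
200 genes, 10 TFs, three conditions with 40/30/14 time points, three
planted complexes of 4–6 members, within-complex correlation 0.8,
background edge probability 0.02 (mean PPI degree ≈ 4), unit background
noise, 2 % missing values.

Each planted complex gets a TF active in 2 of the 3 conditions.  Members
are wired as a random spanning tree plus extra edges (probability 0.3 per
pair); when regulation edges are withheld (`heldout_tr_per_complex`), the
spanning tree covers the *non-withheld* members and each withheld member
attaches to ≥ 2 of them, so the seed-visible part stays connected and the
withheld member remains reachable by extension.  In active conditions
members draw a shared latent profile — a standardized Gaussian random
walk, mimicking time-course autocorrelation — plus i.i.d. Gaussian noise
with variance `(1 − r)/r`, so the expected pairwise Pearson correlation
is `r`; in inactive conditions, and for background genes everywhere,
profiles are independent noise.  TF genes get a +2 mean shift in their
active conditions so the expression-quantile activity caller recovers the
planted activity table.

What the generator does *not* emulate: repression (anti-correlated
regulons), overlapping complexes sharing proteins, false-positive PPI
edges concentrated on hubs, condition-dependent PPI rewiring, and
heavy-tailed expression noise.  Passing the recovery tests therefore
shows the machinery is correct and calibrated, not that real compendia
will yield comparable recovery rates.

## Activity calling

The recommended path is a precomputed activity table (three-column TSV),
e.g. from an upstream activity-tracing tool.  The built-in surrogate
marks a TF active in a condition when its mean observed expression is at
or above the 0.75 quantile of all gene means in that condition
(per-condition threshold; ties active; TFs absent from a condition's
data are inactive).  This implements the "sufficiently high expression
level" criterion transparently but is not a reimplementation of any
specific upstream algorithm.

## Problem sizes and numerical choices

* Null sample size defaults to 10 000 per (condition, `K`).  The
  pipeline-scale synthetic analyses (acceptance script, end-to-end
  recovery tests) use `n_random = 1000` and `n_iter = 1500` annealing
  steps: at 200 genes the standard error of the null mean is far below
  the `α = 1.90` margin of planted seeds (planted scores are ≈ 5–8), and
  desk-scale seeds have ~5 nodes, so 1 500 proposals give every
  beneficial neighbour hundreds of chances.  Unit tests of the null
  itself use the full 10 000.
* All randomness flows from explicit integer seeds; per-(condition, K)
  null streams and per-seed annealing streams are derived by CRC-mixing
  so runs are reproducible bit-for-bit and independent of evaluation
  order.  Re-running a fit with the same inputs and seeds produces
  byte-identical reports.
* Population (ddof = 0) standard deviation in the null; standardizing the
  null sample against its own reference gives moments 0/1 to 1e-9.
* Pearson values are clamped to [−1, 1] against floating-point drift;
  the raw-score oracle agreement is asserted to 1e-12.
* Tie-breaks (dedup order, WCC ordering, trace vertex choice) are
  lexicographic on sorted node lists, never hash order.

## Known limitations

* Activation only: a repressed regulon (coherent *anti*-correlation) is
  invisible to the signed sum score.
* The beam fallback for very large WCCs trades exhaustiveness for
  tractability; candidates it misses are silently absent (logged).
* The connected-null degree bias above means standardized scores from
  graphs with extreme degree heterogeneity are comparable within this
  package but not across null designs.
* Proteins mapping to genes absent from all conditions are dropped
  up front; complexes containing them cannot be found.
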