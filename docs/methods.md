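# Methods

`mkphylo` implements a simulation study that asks how equal-weights parsimony, maximum-likelihood (ML)
Mk inference and Bayesian Mk inference compare on morphology-like
categorical character matrices, once clade support is taken into
account.  This note records the models, the numerical choices, and the
places where the design was genuinely open.

## Generating process

**Trees.** Study conditions use 32-taxon ultrametric generating trees of
root-to-tip depth 1.0 expected substitutions per character: a fully
balanced ("symmetric") topology with equal epoch lengths (five levels of
0.2 each), and a pectinate caterpillar ("asymmetric") topology with
speciation events evenly spaced in time, so every internode has length
1/31.  The depth and the equal spacing are package defaults — the experimental
design fixes only the shapes and ultrametricity (contemporaneous tips) —
and both are configurable through `GeneratingTreeSpec`.

**Characters.** Characters are simulated as nucleotides under
HKY + Γ_continuous and then recoded, which deliberately violates every
Mk assumption used at inference time:

- HKY with transition/transversion parameter κ = 2 and stationary
  distribution π = (0.2, 0.2, 0.3, 0.3) assigned to (A, G, C, T).  The
  assignment puts probability 0.4 on purines, which is what makes the
  R/Y binary recoding land on the (0.4, 0.6) stationary distribution;
  the rate matrix is normalised to one expected substitution per unit
  time at stationarity.
- Per-dataset overall rate r and gamma shape α each drawn from an
  exponential distribution of mean 1; per-character rate multipliers
  are continuous Gamma(α, mean 1) draws (not discretised).
- Binary characters are R/Y recodings (A,G → 0; C,T → 1); multistate
  characters use the fixed bijection A→0, C→1, G→2, T→3.  Each matrix
  contains round-half-even(0.55·n) binary columns (55:45 mix), shuffled.
- Invariant simulated characters are retained; no variability filter is
  applied at simulation time.  Ascertainment correction is therefore an
  inference-side option (off by default for simulated data,
  `variable_only` available for empirical matrices).

**Homoplasy targeting.** The ensemble consistency index
CI = Σ m_c / Σ s_c (m_c = observed states − 1, s_c = parsimony steps on
a tree, invariant characters excluded from both sums) is measured on
each candidate matrix's own most-parsimonious tree.  Rejection sampling
fills user-supplied binned CI quotas; no default target distribution is
shipped, because the reference distribution is cited but not printed
anywhere we can verify — inventing numbers seemed worse than requiring
them explicitly.

**What the generator does not emulate:** missing data,
non-contemporaneous (fossil) tips, among-branch rate variation,
correlated characters.  Passing tests therefore demonstrate method
behaviour under a clean, homoplasy-calibrated generating process, not
performance on real fossil matrices.

## Inference engines

All three engines are implemented in-repo and operate on a shared
compact unrooted-binary tree structure; site patterns are compressed
with multiplicity weights throughout.

**Parsimony.** Fitch scoring vectorised over patterns; multifurcating
trees are scored with Hartigan's generalisation (per node, added cost =
number of children − the maximum state count over children's preferred
sets), which reduces to Fitch on bifurcations.  The search is
random-addition stepwise insertion followed by NNI and optional SPR
hill-climbing; all topologies tying the best score are pooled, then the
tie set is expanded over equal-score NNI neighbours (cap 500, bounded
evaluation budget) so the majority-rule consensus reflects the
most-parsimonious plateau.  Bootstrap pseudo-replicates redraw pattern
weights multinomially (equivalent to resampling characters) and run a
reduced search (fewer starts, NNI only); supports are mapped onto the
splits of the original MP consensus.

**ML Mk.** Transition probabilities use the closed form
p_same(t) = 1/k + ((k−1)/k)·e^(−kt/(k−1)).  Likelihoods are computed by
Felsenstein pruning with a uniform 1/k root distribution, per-pattern
rescaling, and optional 4-category discrete-gamma rate variation
(mean-per-category discretisation; gamma is on by default, with α̂
estimated by bounded scalar optimisation of the profile likelihood on
log α ∈ [log 0.02, log 49]).  Two partition conventions are exposed:
`by_state_count` scores each character with the transition matrix of
its declared state-space size, and `single_matrix` scores everything
with one k = max(k) matrix.  The experiment driver uses
`single_matrix` for the ML engine and `by_state_count` for the Bayesian
engine, mirroring the reported behavioural difference between RAxML and
MrBayes on such data.

Branch lengths are optimised coordinate-wise against cached up/down
conditionals (each edge's likelihood is then an O(patterns) scalar
function, optimised by bounded Brent to 1e−6 within [1e−8, 50]).
Because all branches in a sweep are optimised against the same stale
conditionals, the joint step can overshoot; the sweep direction is
therefore damped by successive halving until the exact log-likelihood
improves, and a non-improving sweep is rolled back.  Topology search is
NNI: a fast pass at current branch lengths, then a slow pass that
re-optimises branch lengths per candidate to escape joint
topology-plus-length optima; multiple starts (NJ on character-mismatch
distances, then random-addition) are available and are used at small
taxon counts where exact optima are checked.  The returned tree is
always strictly binary.  ML bootstrap replicates rebuild their own NJ
start from resampled-weight mismatch distances (with infinitesimal
symmetric jitter to break ties on degenerate flat-likelihood data) so
that replicates are not anchored to a common starting topology.

**Bayesian Mk.** Plain Metropolis–Hastings (no Metropolis coupling —
at 32 taxa single chains mix adequately and the omission is recorded as
a deviation from MrBayes practice) over topology, branch lengths and
gamma shape.  Priors: uniform on resolved topologies, i.i.d.
Exponential(10) on branch lengths (mean 0.1), Exponential(1) on the
gamma shape.  Moves and their Hastings factors:

- NNI across a random internal edge (symmetric);
- SPR: uniform choice of pruned subtree and regraft edge.  The two
  edges flanking the detachment point merge (lengths summed) and the
  target edge splits at u ~ U(0,1); the acceptance ratio carries the
  Jacobian L_target/(l1+l2) of that merge/split parameterisation.  The
  (subtree, target) choice counts are position-independent, so the
  choice probabilities cancel;
- branch-length multiplier l′ = l·e^(λ(u−1/2)) with Hastings l′/l;
- reflecting sliding window on α (symmetric).

Likelihood evaluation is incremental: per-node conditionals are cached
and a proposal recomputes only the path from the perturbed edge to the
root (a full recomputation for α moves).  Chains default to a
neighbour-joining starting topology with one branch-length optimisation
pass — a burn-in-shortening initialisation choice, configurable back to
random starts (used in prior-recovery validation, where the likelihood
is switched off and the sampler must reproduce its priors; this passes
the branch-length-mean and uniform-topology χ² checks).  In multi-chain
runs, chains after the first perturb the start by a configurable number
of random NNIs (default 10): overdispersed starting points let the
pooled split frequencies expose mode-stickiness that a shared start
would hide, which matters for honest posterior probabilities on diffuse
(small-matrix) posteriors.  Convergence is
reported as the average standard deviation of split frequencies (ASDSF,
splits with frequency ≥ 0.1 in some chain), flagged above 0.05 but
never treated as a failure.

The Bayesian point summary is the 50% majority-rule consensus of the
post-burnin topology sample with posterior probabilities as node
support; because retained splits have frequency strictly above 0.5,
collapsing nodes below 0.5 support is the identity on this tree — the
study's observation that Bayesian trees are identical before and after
support assessment holds by construction.

## Tree algebra and scoring conventions

- All split operations are on the unrooted topology; a degree-2 root is
  treated as a subdivision point of one edge (its two child edges carry
  the same split, and a support label on either side covers both).
- Robinson–Foulds distance is the size of the symmetric difference of
  the non-trivial bipartition sets.  Trivial (leaf) splits are excluded
  — RF values then live on the 2(n−3) scale used by the summary tables
  this package emits.
- Resolution counts internal *vertices* of the unrooted topology
  (maximum n−2 = 30 at 32 taxa, matching the saturating value in the
  study's resolution table), not internal edges.
- Majority-rule consensus retains splits with frequency strictly
  greater than the threshold; support collapsing removes supports
  strictly below the threshold (a node at exactly 0.5 is retained).
- Newick internal-node labels above 1 are read as bootstrap
  percentages and divided by 100.

## Scale choices

At full scale the experiment aggregates 1000 replicates per condition
with 250 bootstrap replicates and long chains.  The package defaults are
desk-sized — 20 replicates per cell, 50 bootstrap replicates, short
chains (thousands of generations, sample every 10, 25% burn-in) — and
the test-suite and acceptance runs use those scaled sizes; study-sized
numbers are reachable purely through configuration.  Under strong
signal (1000 characters) short chains started from an optimised
topology concentrate on the same consensus a long chain finds, which is
what the scaled accuracy checks rely on; at 100 characters the
posterior is genuinely diffuse and the scaled runs reproduce ordinal,
not numeric, findings.

## Known limitations

- Parsimony search implements NNI/SPR hill-climbing with random
  addition, not TNT's ratchet/drifting heuristics; at 32 taxa this is
  adequate (it matches exhaustive optima at 6 taxa) but it is not a
  general replacement at hundreds of taxa.
- The ML engine's rate heterogeneity is 4-category discrete gamma while
  the generator uses continuous gamma; exact matching is impossible and
  not claimed (shape recovery is validated to 50% median relative
  error).
- The SPR move is not used when branch lengths are fixed (its
  merge/split bookkeeping changes lengths by construction).
- `single_matrix` mode declares k = max over the matrix; matrices mixing
  state counts are scored with unobservable states for the smaller-k
  characters, which is the point of exposing the mode (it reproduces
  the hypothesised RAxML/MrBayes discrepancy) but is not a recommended
  analysis setting.
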