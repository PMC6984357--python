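# Methods

## Scope and model

phylosel selects the best-fit substitution model for a multiple sequence
alignment by maximum-likelihood scoring of a candidate model space on a
fixed common topology, followed by ranking under information-theoretic
criteria. Candidate models are continuous-time, time-reversible Markov
models of character substitution, `Q_ij = s_ij * pi_j` (i != j), with Q
normalized so that one unit of branch length equals one expected
substitution per site.

For DNA the model space is the classical set of substitution *schemes*:
partitions of the six exchangeabilities (order AC, AG, AT, CG, CT, GT)
into rate classes, written as restricted-growth strings ("000000" = JC,
"010010" = K80/HKY, "012345" = SYM/GTR). The default space crosses the 11
named schemes with {equal, observed} base frequencies and {none, +I, +G,
+I+G} rate heterogeneity - 88 models; 3/5/7-scheme subsets and the full
203-scheme space are available. For proteins the space crosses 17 vendored
empirical replacement matrices (Dayhoff, JTT, LG, WAG, Blosum62, cpREV,
mtREV, mtArt, mtZoa, rtREV, VT, HIVb, HIVw, DCMut, FLU, JTT-DCMut, mtMAM)
with {matrix, observed (+F)} frequencies and the same heterogeneity modes.
Free-rate models (+R(k), 2k-2 free parameters) and per-category-matrix
mixtures (gamma-tied, one shape parameter, or free rates/weights, 2k-2
parameters) are supported by the same machinery; no numerical tables for
the published four-matrix LG mixtures are bundled, so mixtures must be
assembled explicitly from the vendored matrices.

Rate heterogeneity follows the standard discrete-gamma construction:
`ncat` equal-weight categories (default 4) whose rates are the exact
conditional means of Gamma(alpha, alpha) between its quantiles (computed
through the regularized incomplete gamma function, not by quadrature).
The +I class mixes `p_inv * pi_s` over the states `s` compatible with
*every* tip in the column (ambiguity-aware) with `(1 - p_inv)` times the
variable-rate mixture; the gamma rates are not rescaled by `1/(1-p_inv)`.
Ascertainment bias correction is the conditional-likelihood (Lewis)
variant: `lnL_i - ln(1 - P_const)` per site, with `P_const` computed by
pushing the pure constant columns through the same pruning pass. It is
rejected in combination with +I, and on alignments that contain constant
columns.

## Likelihood computation

Site likelihoods use Felsenstein pruning over compressed site patterns,
with conditional likelihood vectors stored per rate category. Ambiguity
codes map to indicator vectors over their compatible states; `-`, `?`,
`N`/`X` are the full state set; `U` is read as `T`. Underflow is handled
by per-pattern rescaling with accumulated log scalers; the rescale check
runs on every third internal node (and the root), which leaves orders of
magnitude of headroom between the trigger threshold (1e-120) and double
underflow. The likelihood is invariant to the placement of the virtual
root (pulley principle), to taxon order, and to pattern compression;
the test suite checks all three plus exact agreement (1e-8) with
brute-force enumeration over internal-node states on trees of up to five
taxa. The inner pruning loop is JIT-compiled with numba when available;
the pure-numpy path computes bit-identical results and is used otherwise.

## Optimization

All models are scored on one fixed topology: neighbor joining on
Jukes-Cantor (DNA) or Poisson-corrected (protein) distances, with branch
lengths re-optimized under every candidate model (a user tree can be
substituted). Scoring all models on a common topology keeps the criteria
comparable and is the standard fast strategy; per-model topology search is
out of scope.

Branch lengths are optimized edge by edge with safeguarded Newton steps
using analytic first and second derivatives in the branch length. The
sweep walks the tree in preorder keeping directional conditional vectors
exact for ancestor edges; per edge, the upper and lower vectors are
projected onto the eigenbasis once, after which every trial length costs a
single small matrix product. Bounds are [1e-8, 100] substitutions/site.

Model parameters use coordinate rounds: exchangeabilities and the gamma
shape are optimized jointly by L-BFGS-B on log coordinates (they are
strongly correlated, and one-at-a-time sweeps contract slowly), with the
proportion of invariant sites *profiled out* at every trial point - for
fixed rates, maximizing over p_inv needs only the cached per-site
variable-rate likelihoods, no new pruning pass. p_inv is bounded above by
the observed fraction of constant-compatible sites. Initialization:
exchangeabilities 1, alpha 1.0, p_inv at half the constant-compatible
fraction, frequencies at observed counts (floored at 1e-4). Rounds stop
when the gain drops below `epsilon` (presets: fast = 1.0, default = 0.01,
thorough = 0.001 log-likelihood units); per-parameter tolerance is 1e-4 on
the transformed coordinate. Bounds: alpha in [0.02, 100], exchangeability
classes in [1e-4, 1000] relative to the class containing G<->T.

When a candidate set is fitted, models are grouped into warm-start chains:
within a frequency mode, a scheme inherits the optimum of the largest
already-fitted scheme that it refines (re-expressing class rates is an
exact continuation - the implied likelihood is unchanged), and +I / +I+G
inherit from their het-predecessors with p_inv started at zero (also
exact). Each fit starts from the best of its warm candidates and the cold
start and can only improve, so the final likelihoods are monotone along
every nested chain by construction, not only up to optimizer noise.
Chains are independent, which makes multi-process execution bit-identical
to sequential execution for any worker count. Models that fail to reach a
finite likelihood are reported as failed and excluded from ranking with a
warning.

## Selection criteria

AIC = -2 lnL + 2K, AICc = AIC + 2K(K+1)/(n-K-1), BIC = -2 lnL + K ln n,
with n = alignment length in sites and K counting free model parameters
*plus* the 2N-3 branch lengths (a uniform convention that leaves rankings
within a fixed topology unaffected; a flag excludes them). Criterion
weights use the delta transform. The decision-theory criterion scores
model i by `sum_j w_j(BIC) * d(tree_i, tree_j)` with d the Euclidean
distance between branch-length vectors on the shared topology
(Robinson-Foulds distance degenerates to zero under the fixed-topology
design); lower is better. Parameter importances sum the weights of the
models containing a parameter; model-averaged estimates renormalize over
those models. Ties in any ranking break by smaller K, then name. The
default reported criterion is BIC; all four are always computed.

## Simulator and the recovery experiment

The built-in simulator draws a random topology by sequential random
addition with i.i.d. exponential branch lengths (mean 0.1
substitutions/site), draws root states from the stationary frequencies,
assigns each site a rate (zero with probability p_inv, otherwise a draw
from the discrete mixture) and propagates states down each branch with
P(t*r). Generating parameters are drawn from documented stand-in ranges:
alpha ~ U[0.3, 2], p_inv ~ U[0, 0.5], exchangeability classes ~ U[0.5, 5]
with transition-containing classes doubled, frequencies ~ Dirichlet(10).
A master seed spawns per-replicate substreams, so any replicate is
individually reproducible.

The recovery experiment draws a generating model uniformly from a
candidate universe, simulates an alignment (DNA: 20 taxa x 2000 sites;
protein: 20 taxa x 1000 sites), runs the full selection pipeline over the
universe and scores an exact best-model name match. The headline numbers
use BIC with the 88-model DNA universe and a 16-model protein universe
({LG, WAG, JTT, Dayhoff} x {none, +I, +G, +I+G}). The acceptance script
runs 30 DNA and 20 protein replicates - a scaled-down replicate count
chosen to keep the full recomputation in the tens of minutes on one core;
the per-replicate design is unchanged, so the estimated recovery fraction
is unbiased for that design, with binomial noise of roughly +-7 points.

What the simulator does *not* emulate: indels and alignment error,
heterotachy (rate variation across lineages), compositional
non-stationarity, and recombination or model variation along the sequence.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model class, not robustness to real-data violations
of it.

## Numerical choices and degenerate inputs

Eigendecomposition operates on the symmetrized `D^{1/2} Q D^{-1/2}`
(guaranteed real spectrum); reconstruction is verified to 1e-10.
Transition probabilities are clipped to [0, 1]. Zero exchangeabilities are
permitted in empirical protein matrices (pairs never observed in the
training data) but rejected for DNA schemes. Saturated distance pairs cap
at 5 substitutions/site; negative neighbor-joining branch estimates clamp
to 1e-8. A two-taxon alignment supports likelihood and distance
optimization (used by the Jukes-Cantor closed-form checks) but not model
selection, which requires at least three taxa. Duplicate sequences are
retained - removal would change n and hence BIC. AICc returns +infinity
with a warning when n - K - 1 <= 0.

## Known limitations

- No per-model topology search; results are conditional on the common
  topology.
- No codon models, covarion models, or nonreversible models.
- The LG4-style published mixture tables are not bundled (see above);
  the mixture machinery is exercised with synthetic mixtures of vendored
  matrices.
- The decision-theory criterion assumes all models share one topology; it
  refuses mixed-topology input rather than falling back to a topological
  distance.
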