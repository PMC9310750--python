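# Methods

`umbelevo` implements a complete macroevolutionary workflow for discrete
inflorescence characters on time-calibrated phylogenies: Mk models of
character evolution, stochastic character mapping, state-dependent
diversification, trait-independent rate-shift detection, and a mixed-data
morphospace. This note records the models, their assumptions, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Characters and trait tables

Trait tables are species x character matrices in the style used for
umbellifer inflorescences: four primary count characters (minimum/maximum
umbellets per umbel, minimum/maximum flowers per umbellet), the derived
*average umbel size*

    [(min umbellets x min flowers) + (max umbellets x max flowers)] / 2,

and six discrete characters (ray equality, flower color, involucral and
involucellar bracts, sepals, ray flowers). Discrete cells are *state
sets*: a singleton is an observation, a multi-member set a polymorphism,
and the full set stands for missing data (`?` in CSV). This coding feeds
straight into likelihoods as ambiguity (partial likelihood 1 for every
member of the set), so no data are imputed or discarded for inference.

Average umbel size is discretized at the tertiles (1/3 and 2/3 empirical
quantiles, linear-interpolation convention) of its observed distribution
into small/medium/large. Values equal to a threshold go to the lower
class; this half-open convention is applied uniformly and logged. The
discretization is invariant under monotone rescaling of the raw sizes.

### Sampling fractions

State-dependent diversification needs, for each character state, the
probability that an extant species in that state is present in the tree.
Because complete state data for unsampled species are unavailable, the
genus-level procedure assumes each genus's sampled state proportions hold
across all its accepted species: for genus *g* with accepted richness
*N_g*, the extrapolated number of extant species in state *s* is
*p_{g,s} N_g*, where *p_{g,s}* is the proportion among the sampled,
determinately scored species. The fraction for state *s* is then (sampled
in *s*) / (sum of extrapolated extant in *s*). Species with missing or
polymorphic focal states are excluded from the proportions. Genera that
are monomorphic among sampled species are treated as monomorphic overall,
which follows directly from the extrapolation. Allocating a polyphyletic
genus's unsampled species across its subclades proportionally to sampled
subclade size leaves these per-state totals unchanged, so the aggregate
fractions do not depend on how polyphyly is resolved.

## Mk models

A character with *k* states evolves along the tree as a continuous-time
Markov chain with generator Q (off-diagonal rates in events/Myr, rows
summing to zero). Parameter sharing gives ER (one rate), SYM (one rate
per unordered pair), and ARD (one per ordered pair); an *ordered*
character restricts transitions to neighbors on a chain, e.g. floral <->
absent <-> hyperfloral, so a 3-state ordered ARD model has 4 free rates.

For two ordered 3-state characters analyzed jointly, the combined chain
lives on the 9 paired states and moves change exactly one character by
one step (24 directed edges). In the *uncorrelated* variants a move in
one character shares its rate across the resting states of the other
(ARD 8, SYM 4 parameters); in the *correlated* variants the rate depends
on the partner's resting state (ARD 24, SYM 12). These counts are the
package's reconstruction of the combined-matrix structure from the
published parameter counts, which they match exactly.

Likelihoods use Felsenstein pruning with per-branch transition matrices
exp(Qt), computed by eigendecomposition with a scaling-and-squaring
fallback for defective Q; partials are rescaled per node with accumulated
log factors. Polytomies are handled as products over all children. The
root is combined under a configurable policy: equal weights (default),
the stationary distribution of Q, or conditional (FitzJohn-style)
weighting; outputs record the policy because none of the three is
canonical for these data.

Fitting maximizes the likelihood over log-transformed rates with
multi-start L-BFGS-B in the box [1e-9, 100] events/Myr (default 10
starts; rate surfaces of ARD models can be multimodal). Model selection
uses AICc with n = number of tips, which reproduces the published
model-selection arithmetic; models within 2 AICc units of the best are
flagged jointly best. A handful of published table cells are *not*
reproducible from their own printed lnL and parameter counts under this
formula (the 2-parameter ordered SYM row for umbel size and the four
combined-character rows, plus two rows of the diversification table); the
package reproduces the formula, not those cells.

Marginal ancestral states are computed by the standard two-pass
algorithm; each internal node's distribution equals the
clamp-and-renormalize definition, verified against exhaustive enumeration.

## Stochastic mapping

Full character histories conditional on the tip data and a fixed Q are
drawn by (1) sampling node states from their joint conditional
distribution - root first, then each child given its parent against the
downward partials - and (2) sampling each branch path from the chain
conditioned on its endpoints by uniformization (the dominated-Poisson
construction): the number of jumps is drawn from its exact conditional
distribution, jump states by backward products of powers of the
uniformized kernel, jump times as uniform order statistics, and virtual
jumps collapsed. Uniformization is exact for any generator and branch
length, so no rejection fallback is required. Polymorphic and missing
tips get a state drawn per map from their conditional distribution
restricted to the allowed set.

Transition counts are tallied per ordered state pair per map; the
reported "95% interval" is the 2.5-97.5 percentile of per-map counts
(a mean +/- 1.96 sd interval is also emitted, since either reading of a
mapped CI appears in practice). Map-averaged node-state frequencies
converge to the marginal ancestral probabilities, and single-branch mean
change counts converge to rate x time; both are asserted in tests.

## State-dependent diversification

The SSE family is parameterized by turnover tau = lambda + mu and
extinction fraction eps = mu / lambda per (observed, hidden) state, with
transition rates q over the expanded state space and per-observed-state
sampling fractions f entering the tip conditions (D = f for compatible
states, E = 1 - f). D is set to f in *every* compatible hidden copy -
the convention of the established hidden-state SSE implementations -
because dividing by the hidden-class count would shift lnL by a per-tip
constant that differs between models with different numbers of hidden
classes and would corrupt AICc comparison across the model set.

The twelve multistate models are: MuSSE-equivalent (no hidden states),
MuCID-3 (three diversification classes unlinked from the observed
character - the character-independent null), MuHiSSE with a hidden state
attached to one observed state at a time, and MuHiSSE with all states
split; each with shared ("constrained") or free extinction fraction.
Transition structures: MuSSE, 4 ordered rates; MuCID-3, 4 ordered rates
per class plus 6 class-switch rates (18) - i.e. "hidden traits = 2" is
read as three diversification classes, the reading that matches the
published transition-parameter count; one-state MuHiSSE, 4 shared
observed rates plus 2 hidden switches (6); all-states MuHiSSE, 4 rates
per class plus 2 shared switches (10). The binary set (BiSSE-like,
CID-2, CID-4, HiSSE) mirrors these with 2 observed states; CID-4 uses a
single class-switch rate.

Along each branch the coupled extinction/data ODEs are integrated
rootward. E and D are integrated *jointly* per branch (E initial values
at a node are taken from its children, which agree by construction), so
no global extinction interpolant is needed. The integrator is a
branch-batched classical Runge-Kutta scheme in which all branches at the
same tree depth advance together and the per-branch step count scales
with branch length x total rate divided by `step_scale` (default 0.03;
fits use 0.1). This replaces per-branch adaptive solver calls, which
profiling showed to be two orders of magnitude slower at equal accuracy;
the scheme is validated against (a) the constant-rate birth-death closed
form, (b) the exact factorization lnL_SSE = lnL_BD + lnL_Mk when all
states share (tau, eps) and f = 1, and (c) a 30x finer integration, all
to 1e-6 or better at the default settings. D is renormalized at each
node with accumulated log scalers. The root uses conditional (FitzJohn)
state weighting with survival conditioning (divide by lambda_i (1 -
E_i)^2) by default; equal weighting is selectable.

Fits use multi-start L-BFGS-B on log parameters with boxes tau in
[1e-6, 50], eps in [1e-6, 3], q in [1e-9, 10] per Myr. The
false-positive experiment in the test suite simulates equal-rates data
(a birth-death tree with an independently evolving character) and checks
that the character-dependent MuSSE model rarely beats the
character-independent null by more than 2 AICc units. The null used
there is MuCID-1 - one diversification regime shared by all states, the
degenerate member of the MuCID family - because against MuCID-3 alone
the comparison under a homogeneous truth is decided entirely by the
14-parameter count difference rather than by any property of the data.
MuCID-3 and the rest of the twelve-model set are built and fit through
the same interface.

## Trait-independent rate shifts

The stepwise shift finder partitions the tree into pieces, each under its
own Yule or birth-death process (or the better of the two per piece,
"mixed"). A piece's log-likelihood combines flow factors along its
resolved branches, a factor lambda per speciation node (lambda^(c-1) at
polytomies), and unresolved-clade richness probabilities at its tips:
P(n | stem age t) in geometric birth-death form, whose Yule case is
e^{-lambda t}(1 - e^{-lambda t})^{n-1} and whose sum over n >= 1 equals
the survival probability 1 - E(t). Per-tip richness is derived from
genus-level accepted counts by distributing unsampled species evenly
among a genus's sampled tips (floor/ceil with the remainder assigned by
label order). Yule pieces with unit richness have a closed-form MLE;
birth-death pieces are fit numerically with eps = mu/lambda < 1.

The greedy search tries stem and crown placements at every candidate
node, refits only the two affected pieces, and accepts the best shift if
it improves the total AICc (k = piece rate parameters + one per shift
location) by at least a threshold. Two guards matter:

- **Candidate clades need >= 5 tips** (configurable). The crown piece of
  a tiny clade has a likelihood that grows without bound as its crown age
  shrinks (a rate estimated from one waiting time), so unrestricted
  candidate sets accept spurious shifts on short cherries regardless of
  any threshold.
- **The default threshold is 2 ln(candidate count)**, a Bonferroni-style
  correction for scanning hundreds of nested alternatives per sweep - in
  the same spirit as the tree-size-calibrated cutoff used by the
  established stepwise implementation. A flat cutoff (e.g. 2) can be
  supplied but has no multiplicity control and floods homogeneous trees
  with false shifts.

With these defaults, homogeneous 200-tip pure-birth simulations yield
zero shifts in >= 90% of replicates while a 5-fold rate increase in a
50+ tip clade is recovered at (or adjacent to) the true node.

## Morphospace

The mixed PCA standardizes quantitative columns to zero mean and unit
population variance and expands each qualitative character into its
centered indicator matrix with level columns divided by sqrt(level
frequency); with uniform row weights 1/n this makes the spectrum sum to
p_quant + sum(levels - 1) and assigns one eigenvector per trait or
state. Rows with any missing cell among the analyzed characters are
dropped listwise (counted and logged) - the decomposition needs complete
rows and no imputation is attempted. Polymorphisms must be resolved
first; the resolution-replicate summary (eigenvalue spread and
sign-aligned between-replicate score correlations) quantifies how little
the ordination depends on which member state is chosen. Component signs
are fixed by making the largest-magnitude loading positive.

Structure detection compares eigenvalue-dispersion statistics against
column-shuffled nulls: psi is the eigenvalue variance sum(l_i - mean)^2/N
and phi = psi / (mean^2 (N-1)) its normalization to [0, 1] (0 = flat
spectrum, 1 = all variance in one component). The source these
statistics follow does not print formulas, so these definitions are this
package's operationalization; they are used only comparatively (observed
vs randomized), which is insensitive to the exact scaling.

## Synthetic data

The generators provide every input with known truth: constant-rate
birth-death trees (forward simulation from a crown pair; n-conditioning
stops at a uniform time inside the first interval with n extant lineages
- approximate conditioning, adequate for testing but not for
benchmarking tree priors), Gillespie character histories recording every
event, joint state-dependent simulations (per-state speciation,
extinction, and anagenetic change in one event stream, extinct lineages
pruned with paths concatenated), and trait matrices shaped like the real
coding scheme. Discrete characters in synthetic matrices are tied to a
latent pseudanthial syndrome (absent / floral / hyperfloral) so the
matrix carries genuine correlation structure for the morphospace tests;
count characters are log-normal. Default missing (5%) and polymorphism
(2%) rates are plausible for compilation-based morphological matrices
and are freely configurable. Every simulator takes an explicit seed and
is bit-for-bit reproducible.

What passing on synthetic data shows - and what it does not: the
simulators match the inference models' assumptions (constant rates,
no rate heterogeneity beyond what is modeled, correct ultrametry),
so recovery there demonstrates correctness of the implementation, not
robustness to the model violations real chronograms carry (dating error,
unmodeled heterogeneity, non-random missing data, correlated sampling).

## Problem sizes and tolerances

The test suite runs enumeration oracles at <= 6 tips, closed-form SSE
checks at 50 tips, mapping calibration at 10,000 single-branch maps and
5,000 maps on 20 tips, rate recovery at 500 tips, SSE null experiments
at 20 replicates of 50 tips, and shift-finder experiments at 20
replicates of 200 tips - sizes chosen so the full suite completes on a
single core in minutes while every statistical assertion retains a
comfortable Monte Carlo margin (3-4 standard errors, or success counts
with binomial slack). `scripts/acceptance.py` re-runs the same stages
from scratch at comparable sizes.

An optional script, `scripts/full_data_analysis.py`, runs the published
full-data workflow (ordered ARD fit, 500 stochastic maps, mixed PCA) on
a user-supplied chronogram and trait table; it requires externally
downloaded data and is not part of the test suite.

## Known limitations

- No Bayesian machinery: no MCMC over Q, no reversible-jump shift
  posteriors, no joint sampling of maps and rates.
- No hidden-rate-category Mk models; hidden states exist only inside the
  SSE family.
- The shift finder ignores cross-piece speciation events at piece
  boundaries (the standard simplification of stepwise piecewise
  birth-death fitting).
- Mixed PCA has no phylogenetic correction; scores are species-level.
- Zero-length branches are rejected rather than jittered; trees must be
  pre-cleaned.
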