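# Methods

This note records the models implemented, the numerical choices made where
the design was genuinely open, what the synthetic data do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Dollo reconstruction and the loss likelihood

A domain is assumed to arise exactly once and be lost whole-lineage at a
Poisson rate λ (losses/My). The origin is the edge above the MRCA of the
present species; when the presences span the root, the origin is a virtual
zero-length stem above the root, which makes origin assignment total.
Within the origin clade, the basal edge of each maximal subtree containing
no present species is a loss edge (index *j*); every other edge is a
retention edge (index *k*); edges below a loss edge are excluded entirely.

Three conventions matter and are deliberate:

* **The origin edge itself is neither a retention nor a loss edge.** The
  domain arises at an unknown point along it, so it is not a retention
  interval of known length, and it cannot carry a loss.
* **The parsimony initialization** divides the loss count by the summed
  retention length (Σtₖ). An alternative denominator — the full branch
  length of the origin clade — is available
  (`parsimony_init_rate(..., denominator="total")`); the retention
  denominator is the default because it matches the likelihood's index
  sets.
* **Zero-length loss branches** (possible when dated trees resolve
  polytomies with zero-length edges) are dropped from the likelihood
  product: a loss on a zero-length branch has probability zero under the
  continuous model, so the factor would otherwise annihilate the
  likelihood at every rate. The loss still counts toward the parsimony
  initialization.

Polytomies are handled as given; no resolution is attempted.

The maximizer runs Newton iteration on log λ (which enforces positivity)
with step-halving, stopping when the log-likelihood moves < 1e−10 or after
100 iterations, and falls back to bounded scalar minimization on
[init/100, 100·init] if the curvature becomes unusable. Zero-loss domains
return λ̂ = 0 exactly rather than a small floor. Estimates above 1 loss/My
are treated as runaway fits driven by unmodelled false positives and reset
to the parsimony initialization (with that rate's own likelihood).

A calibration caveat, asserted in the tests: on a 64-tip, 800-My tree with
the data set's own ascertainment (patterns observable in ≥ 2 species), the
median estimate tracks the truth within a factor of ~2 at realistic rates
(1e−4 to 1e−3/My) but falls to roughly a quarter of the truth at 1e−2/My,
where conditioning on survival plus Dollo undercounting dominates. Loss
rates near or above 1e−2/My should be read as order-of-magnitude
statements.

## False-positive model

The joint likelihood multiplies the loss likelihood refit on the retained
species by Bernoulli prior terms for each evidence class (coding f_c,
intergenic-only f_i). The search proposes flips at the granularity of
maximal monophyletic all-present clades, accepts the single best improving
move (falsifying a clade, or restoring a previously falsified one), and
stops when nothing improves; clades are recomputed after every acceptance
because flips can merge or split them. Ties break toward the smallest
clade, then the lexicographically first species, for determinism. A flip
that would leave a domain with no presence at all is forbidden — a domain
with no true presence has no likelihood.

The outer empirical-Bayes loop pools flip counts over all domains and
updates f_c = Σ|F_C|/Σ|P_C| and f_i = Σ|F_i|/Σ|P_i| (species counts,
matching the likelihood's exponents; clade counts would be the other
defensible reading). Priors are floored at 1e−9 to keep logs finite, and
iteration stops when both move < 1e−6 (typically 2–4 rounds).

Two behaviors worth knowing: a genuinely isolated *true* presence is
rationally flagged under a generous prior — indistinguishable from a false
positive by construction — so on clean sparse data the intergenic prior
collapses toward, but not exactly onto, the floor; and the greedy search
is locally optimal, reaching the exhaustive-best likelihood on ≥ 95% of
small fixtures (asserted) but not guaranteed globally.

## Contamination screen

For each occupancy *n*, 20,000 (configurable) random placements of *n*
presences give the null mean and SD of the Dollo loss count;
z = (observed − mean)/SD, computed with and without the intergenic-only
species. A domain is excluded when it occupies fewer than half the species
and its worse z falls on the excluded side of the threshold.

The direction is configurable, and deliberately so. Under this natural z
definition, clade-coherent (vertically inherited) patterns have far fewer
losses than random placements and score strongly *negative*; patterns that
look like random scatter score near zero. The published rule as literally
printed (exclude z < −2) therefore flags coherent patterns, which is the
opposite of its stated purpose of removing distributions indistinguishable
from chance — the source does not print its z formula, so its orientation
cannot be reconstructed. The default follows the literal rule
(`direction="less"`, threshold −2), which is also the direction under
which the screen's calibration property is well-defined (null-drawn
patterns excluded at the nominal tail rate); `direction="greater"`
implements the stated purpose instead. Null tables are cached per
occupancy with per-*n* seeds derived from the base seed, so results do not
depend on request order.

## Clustering statistic

The raw statistic for one reading frame is the index of dispersion
var/mean (population variance) of hydrophobic counts (L, I, V, F, M, W) in
non-overlapping blocks of six residues, averaged over the six frames
(truncated tail blocks dropped). The normalization divides by the
expectation of the same frame-averaged statistic under uniformly random
placement of the observed number of hydrophobic residues in the observed
length.

That expectation is closed-form. Conditional on *s* hydrophobics falling
in a frame's window of n = 6B positions, the block counts are multivariate
hypergeometric with mean exactly s/B, and

    E[ var(c)/mean(c) | s ] = ((n−6)/(n−1)) · (1 − s/n).

The per-frame null averages this over s ~ Hypergeom(L, m, n) conditioned
on s ≥ 1. Because the denominator is deterministic given (L, m), the score
has expectation exactly 1 under random placement — the calibration the
tests assert. A permutation null (`null="permute"`) is retained as an
independent cross-check and agrees with the closed form within Monte Carlo
error (asserted).

Degenerate inputs: sequences with no hydrophobic residues, or too short
for any frame to hold two complete blocks (length < 12), are undefined and
propagate as missing — never as 0. Per-domain clustering is the unweighted
mean over all instances in the data set, so species contributing more
instances weigh more; the same convention applies to ISD.

## Transformations and breakpoint regression

Loss rates are transformed with a two-parameter Box–Cox
((x+λ₂)^λ₁ − 1)/λ₁ fitted by profile likelihood (normal log-likelihood of
the transformed values plus the Jacobian). With exact zeros in the data
(lossless domains) the profile likelihood diverges as λ₂ → 0, a known
pathology of the two-parameter form; the shift is floored at 1e−3 times
the smallest positive value. Instance counts use the one-parameter form
(via scipy's standard fit), applied after rather than before averaging so
the averaged quantity keeps its natural linear units.

The breakpoint model is continuous piecewise-linear,
y = β₀ + β₁x + β₂(x−ψ)₊. ψ is profiled over ≥ 200 grid points spanning the
interior 5th–95th percentile of x with bounded local refinement. Its 95%
CI inverts the SSE profile through the χ²(1) likelihood-ratio bound; a
Wald interval from the numerical curvature of the profile is reported
alongside. Adjusted R² uses the Wherry formula with three predictors (x,
the hinge, and ψ). The comparison against the no-breakpoint model uses the
Davies bound — the breakpoint is unidentified under the linear null, so
the naive F-test is anticonservative (measured ~12% rejection at nominal
5%; the Davies bound measures ~4%) — while the zero-slope-on-one-side
alternatives, which share the breakpoint, use ordinary nested F-tests.
The naive F p-value is still reported as `p_vs_linear_f`.

Cohort variability regresses within-cohort trait SD on cohort age by
weighted least squares with weights equal to cohort size, dropping
singleton cohorts.

## Trend simulation

The differential-retention simulation resamples a young cohort's trait
values with replacement (default n = 5,000), assigns each domain the loss
rate its trait predicts — the piecewise-linear prediction on the
transformed scale, inverted through the fitted Box–Cox and floored at
1e−6/My, since back-transformed predictions can otherwise be non-positive
— draws one exponential time-to-loss per domain with mean 1/rate, and
records survivor trait mean and SD at each checkpoint. The survivor
distribution at time T is exactly the initial distribution reweighted by
exp(−rate·T); the tests assert agreement with that oracle within Monte
Carlo error, alongside the qualitative pattern (survivor mean converges
monotonically toward the rate-minimum trait; SD declines).

## Synthetic data

The generator's defaults are the study conditions: a 64-tip pure-birth
ultrametric tree of depth 800 My; per-domain ISD ~ Beta(2,8) (mean 0.2)
and clustering ~ Normal(1, 0.25) truncated at 0; a V-shaped log-rate map
with its minimum 7e−4/My at ISD 0.18 and slopes −2.0/3.86 per trait unit,
giving a median loss rate near 1e−3/My; origin edges chosen by domain age
(the oldest edge whose start time is at or below the age, ties by index);
per-branch loss with probability 1 − exp(−tλ); and false positives planted
among absent species so the expected *fraction of presences that are
false* is f_c = 2.1e−4 (coding) and f_i = 0.031 (intergenic) — the
quantities the EB loop estimates. Recovery fixtures raise f_i to 0.2 and
f_c to 1e−3 so that planted errors are numerous enough to measure recall
and precision. Domains losing every species are redrawn (observation
conditions on survival); redraw counts are kept in the truth table so the
ascertainment bias itself stays measurable.

The young cohort used to initialize trend simulations is drawn from
Beta(4,6) (mean 0.4): young domains are born disordered, and differential
retention — not a change in birth traits — is the mechanism under test.

Sequences place a binomial number of hydrophobic residues (fraction 0.3,
length 120) uniformly at random for a clustering target of 1, in
Poisson-length runs for targets above 1, and by jittered stratified
spacing for targets below 1. Realized scores track the target
monotonically but are not calibrated to equal it away from 1.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic sequence evolution (sequences are
i.i.d. draws, not homologs); correlated loss across domains; rate
variation across branches or time; gene-tree/species-tree discordance;
annotation error that is phylogenetically clustered (planted errors are
independent across species); and the coupling between domain age and trait
values that real phylostratigraphy data carry.

## Problem sizes

Default validation sizes: 200 domains on 64 tips for the EB and
quality-control checks, 5,000 points for breakpoint recovery, 5,000
simulated domains over 2,000 My for trends, 2,000–20,000 replicates per
screen null table, and exhaustive sweeps over all presence subsets of
4–8-tip fixture trees for the Dollo oracle. These sizes give the
assertions comfortable Monte Carlo margins while keeping the whole suite
in seconds.

## Known limitations

* Dollo undercounts multiple losses on one branch; the likelihood refit
  corrects this only partially (the estimate is never far below the
  parsimony rate, and the bias grows with rate — see the calibration
  caveat above).
* The false-positive model treats annotation error and horizontal
  transfer identically, and models false *negatives* not at all (the
  intergenic evidence class is taken as given).
* The breakpoint CI is a profile interval under i.i.d. normal errors on
  the transformed scale; heteroskedasticity is not modelled.
* Mixed-effects (age-as-random-effect) robustness models are out of
  scope; the cohort-keyed tables the pipeline exports allow fitting them
  with standard tools.
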