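# Methods

`traitdiv` implements the comparative-phylogenetics pipeline used to ask
whether a three-state ecological character (discretised body size, or dietary
ecotype) is associated with diversification on a time-calibrated phylogeny.
This note records the models, the numerical choices, what the synthetic-data
generators do and do not emulate, and the design decisions that were
genuinely open.

## Trees and trait coding

Trees are rooted, ultrametric, with branch lengths in millions of years (my).
Newick/NEXUS I/O goes through dendropy; internally trees are flat
parent/child/branch-length arrays for the likelihood kernels.  Ultrametry is
checked as (max − min root-to-tip depth) ≤ tol × depth, boundary inclusive,
default tol = 1e-6 relative.

Continuous size is discretised by **gap coding**: the k−1 class boundaries go
into the k−1 widest gaps between consecutive distinct sorted values.  Two
conventions had to be fixed because only class ranges, not the rule's
internals, are conventionally reported: each breakpoint is the midpoint of
its gap, and ties between equally wide gaps are resolved toward the smaller
value.  Both are deterministic and tested against an oracle that enumerates
every possible breakpoint placement.

Three-state characters are re-expressed as two binary presence/absence
characters for the SSE machinery: first extreme (small, benthic) = `01`,
second extreme (large, pelagic) = `10`, intermediate = `11`.  The fourth
combination `00` is never observed and is excluded from the state space
entirely rather than carried as a latent state; this keeps the composite
state space at 3 × H and avoids estimating rates into a state no tip can
occupy.

## Mk models, ancestral states, stochastic maps

Discrete characters evolve under a continuous-time Markov (Mk) process with
ER / SYM / ARD sharing structures, plus *constrained* variants that zero the
direct rates between the two extreme states so every path runs through the
intermediate.  The likelihood is Felsenstein pruning with per-branch
P(t) = expm(Qt) computed by scaling-and-squaring — deliberately not an
eigendecomposition, because masked rate matrices can be defective.  Root
treatment defaults to FitzJohn state-frequency weighting with uniform and
stationary options; the same choice is exposed for the SSE engine so the two
model families are comparable.  Ambiguous or missing tip states are all-ones
partial likelihoods.

Fitting maximises the pruning likelihood over log rates (bounds 1e-9 to 1e3
per my) by multi-start L-BFGS-B, 10 random starts by default, drawn
log-uniformly around the characteristic scale 1/tree-depth.

Marginal ancestral states use the standard re-rooting (inside × outside)
algorithm; with the FitzJohn root the weights are held fixed at the
root-state data frequencies, which matches the enumeration posterior on
small trees to < 1e-8.

Stochastic maps are sampled by backward pruning / forward node-state
sampling, with within-branch histories drawn conditional on branch endpoints
by **uniformization** (number of jumps from its exact conditional
distribution, jump chain by backward powers of the uniformized matrix,
virtual jumps collapsed).  Uniformization was chosen over rejection sampling
because it stays exact and cheap when endpoint states differ and rates are
small — exactly the regime the constrained models produce.  Transition
counts are reported three ways — per-map integers, across-map means, and
per-pair modal counts — because a single reported integer per pair can be
read as any of the three.

## Phylogenetic signal

Blomberg's K uses the MSE-ratio form with the phylogenetic GLS mean and the
Brownian-motion expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n−1).  The permutation
p-value permutes tip labels and compares the phylogenetically-scaled MSE
(not K itself), as in the standard implementation; p gets the (r+1)/(N+1)
continuity correction.

Continuous Pagel's λ scales the off-diagonal of the Brownian covariance and
is fitted by profile ML (analytic profiling of mean and rate; a 21-point
grid locates the basin before bounded refinement, and the boundaries λ = 0,
1 are checked explicitly).  The λ = 0 test is a likelihood-ratio test on
χ²(1).  λ = 0 sits on the boundary of the parameter space, so χ²(1) is
conservative; an optional halved p-value (the 50:50 mixture) is exposed but
off by default.  Discrete λ applies the corresponding branch-length
transform — internal branches × λ, terminal branches stretched to preserve
tip depths — inside a joint ML fit of λ and the Mk rates; the Mk structure
inside the discrete-λ fit defaults to ER (the cheapest structure whose λ is
well identified; ARD is supported).

The phylogenetic ANOVA computes the ordinary one-way F and calibrates it
against F values from Brownian simulations on the tree, with the Brownian
rate set to its ML estimate from the observed response.  Published p-values
of this test depend on the original data set and are not reproduction
targets; the package instead verifies the test's type-I error calibration
under the null.

## The SSE engine

The multistate hidden-state speciation–extinction likelihood integrates, per
branch and backward in time, the standard coupled equations for extinction
probabilities E_i(t) and data partials D_i(t) over K = 3 × H composite
states, with tip initialisation D = ρ(observed state) on matching composites
and E = 1 − ρ; at nodes D combines as λ·D_left·D_right; the root uses
FitzJohn weights and conditions on survival of both root lineages
(`lnL = log Σ w_i D_i / (λ_i (1−E_i)²)` plus accumulated rescaling logs).
Diversification is parameterised as turnover τ = λ + μ and extinction
fraction ε = μ/λ.  Net diversification is reported as λ − μ (the standard
definition; τ and ε are the fitted quantities).

Integration is an adaptive Dormand–Prince 5(4) stepper compiled with numba,
rtol 1e-8 / atol 1e-10, with D rescaled at every branch top and node to
prevent underflow on deep trees.  The engine is validated four independent
ways: against the closed-form Yule likelihood (single state, μ = 0);
against the exact factorisation lnL(SSE) = lnL(birth–death) + lnL(Mk) when
diversification is state-independent; against a fixed-step classic RK4
integrator at step 1e-5 on two-tip trees; and marginal reconstructions
against a pin-the-node-state brute-force recomputation on four-tip trees.

Marginal ancestral reconstruction exploits the linearity of the D system
given E: each branch gets a K × K fundamental matrix (integrated with the
same stepper), and transporting the root weights through the transposes
yields the outside vectors; marginal ∝ inside × outside, normalised per
node.

### The eight-model set

Per trait the factory builds: an equal-rates null ("Dull"); MuSSE (τ, ε per
observed state); MuHiSSE (τ, ε per observed × hidden state, H = 2) and a
*relaxed* variant adding one free directional hidden-transition rate (the
minimal single-parameter relaxation); two absorbing variants (all observed
transitions out of one extreme state zeroed); and character-independent
CID2/CID3 nulls (τ, ε tied to hidden classes only, H = 2 or 3).  All models
share the constrained observed-transition mask (4 free observed rates shared
across hidden classes) and a single hidden-class rate; hidden moves change
only the hidden class and observed moves only the observed character — no
dual jumps.  Absolute free-parameter counts depend on accounting
conventions that differ among implementations of this model family, so the
factory is audited for the structural patterns that are convention-free:
"Dull" has the fewest parameters, Relaxed = MuHiSSE + 1, CID3 = CID2 + 2,
and the absorbing variants sit below MuHiSSE.  "Dull" keeps the 4-rate
constrained transition structure while sharing all diversification
parameters — the null is about diversification, not transition asymmetry.

Fitting is multi-start L-BFGS-B over log τ ∈ [1e-4, 10], log ε ∈ [1e-6, 3],
log q ∈ [1e-6, 1] (per my); default 25 random log-uniform starts, with more
available for rugged surfaces (the tests use fewer because the surfaces at
desk scale are low-dimensional).  Models are ranked by AIC, with AICc
computed alongside (the two orderings rarely differ at these parameter
counts and tree sizes).  Akaike weights
ω_m = exp(−Δ_m/2)/Σ exp(−Δ_k/2) feed model-averaged per-node rates:
rate(node) = Σ_m ω_m Σ_i P_m(i|node) · rate_{m,i}, a convex combination
that is bounded by the contributing models' rates by construction.  Every
model with ω above a threshold (default 1e-3) must supply a reconstruction.

## Lineage-through-time diagnostics

The γ statistic is computed from internode intervals g_j (duration with j
lineages) and cumulative sums T_k with the usual standardisation; it is
scale-invariant and requires a bifurcating ultrametric tree.  The LTT time
axis is negative before present (root most negative).  The constant-rates
test simulates pure-birth trees conditioned on the tip count (interval j ~
Exp(jλ), including the final interval by memorylessness); the MCCR variant
grows trees to the full clade size N and prunes uniformly to the sample
size n, which shifts the null γ downward as sampling drops — the direction
the test exists to correct.  One-tailed p = (r+1)/(N_reps+1) for r null
values ≤ observed, so p is never exactly 0.  A birth–death null is exposed
as an option; pure birth is the default, matching the test's original form.

## Synthetic data

The generators exist so that every stage is testable without downloads, and
their defaults encode the study design they emulate: a ~300-tip tree (the
order of the real 345-taxon tree), three observed states with constrained
transitions, two hidden diversification classes, and per-state sampling
fractions (0.72, 0.68, 0.76).  The state-dependent birth–death simulator is
an exact Gillespie process from a bifurcating root; in target-tip-count mode
the present is drawn uniformly inside the interval during which the target
count holds, extinct lineages are pruned, tips are thinned per-state by ρ,
and trees outside ±20% of the target are rejected (budget 1000 tries —
note this rejection mildly biases realised trees when extinction is
strongly asymmetric).  True transition counts and per-state occupancy times
are retained so transition counting can be validated against q·t
expectations without inference.  Discrete traits on a fixed tree evolve by
exact CTMC path sampling; continuous traits are multivariate Gaussian draws
with covariance σ²C(λ).  The full trait-table generator draws total length
as a *clustered* lognormal — a latent small/medium/large class evolving
under the constrained Mk process, class centres 6.8/12.2/22 cm, plus a
within-class Brownian deviation (log-variance 0.004) — because gap coding
is only meaningful on clustered data; a smooth unimodal size distribution
would make the discretisation, and everything downstream of it,
degenerate.

What the generators do **not** emulate: fossil/extinct sampling,
among-lineage rate heterogeneity beyond the hidden classes, measurement
error in traits, cladogenetic (speciation-coincident) character change, and
non-uniform taxon sampling within a state.  Passing calibration tests on
these generators therefore shows the estimators are correct under their own
assumptions, not that those assumptions hold for any particular empirical
data set.

## Problem sizes in the test suite

The statistical calibration tests run at sizes chosen to keep the suite
quick while leaving the checks meaningful: Blomberg's K averaged over 40
Brownian replicates on 128 tips (band 0.80–1.20); λ recovery at λ = 0.5
with 20 replicates of 256 tips (median in 0.3–0.7); ANOVA type-I error over
150 null replicates with 300 simulations each (band 0.01–0.11); MuSSE
turnover-order recovery ≥ 6/8 replicates at 150 tips; CID-vs-state-dependent
selection sensitivity and specificity ≥ 4/6 each at 150 tips.  The fuller
experiment (100–400 replicates, 300 tips, the spec-scale bands) uses the
same code paths with larger constants.

## Known limitations

* Polytomies are accepted by the tree layer and the Mk machinery but not by
  the SSE engine or γ (both require bifurcating trees).
* The discrete-λ transform and the SSE engine require ultrametric trees.
* FitzJohn root weights are treated as fixed in marginal reconstructions
  (standard practice; exact only up to that convention).
* AICc small-sample correction uses n = number of tips, a convention, since
  the effective sample size of a phylogeny is undefined.
* The SSE optimiser uses finite-difference gradients; with ≥ 20 parameters
  and few hundred tips a fit takes seconds to minutes, not milliseconds.
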