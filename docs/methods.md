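# Methods

## Model

A single migrant haplotype enters a resident haploid population of constant
size `N` that evolves by a Moran process: at every event one individual is
chosen uniformly to reproduce and one is chosen to die with probability
proportional to `1 − σ`, where `σ` is the Malthusian fitness (wildtype
`σ = 0`).  The migrant carries one beneficial allele, `I` linked deleterious
alleles to its left, `J` to its right, and `F` unlinked deleterious alleles.
A carrier haplotype is labelled by its class `(i, j; f)` — the counts of
deleterious alleles it still carries.  `σ_(i,j;f)` may be supplied as an
explicit table or built additively from per-allele costs.

Recombination happens at birth.  Among the linked loci a single crossover is
assumed, so one recombination event removes a contiguous block from one side:
class `(i, j)` can move to `(k, j)` with `k < i` or to `(i, k)` with `k < j`,
with per-birth probabilities `r^(i,j)_(target)`; `r_(i,j)` denotes their sum.
Because carriers are rare throughout the stochastic phase, the partner is
effectively always a wildtype resident, so recombination only ever *removes*
deleterious alleles.  Each unlinked allele is transmitted independently with
probability 1/2 (binomial inheritance).

Two recombination parameterizations are provided: a `matrix` mode giving each
`r^(i,j)_(target)` explicitly (which may depend on the source class), and an
`interval` mode where each entry is the probability of a crossover falling in
the interval between adjacent linked loci, independent of the source class.
`uniform` is the special case of equal interval probabilities.

## Stochastic phase: extinction and rescue

While carriers are rare, lineages are independent and the carrier dynamics
form a *reducible* multitype branching process (types only move toward fewer
deleterious alleles).  The extinction probability `Q_(i,j;f)` of a single
`(i, j; f)` founder therefore satisfies a triangular system: processing
classes in increasing order of `i + j` and then `f`, each `Q` solves a scalar
quadratic

    a Q² − b Q + c = 0,
    a = (1 − r_(i,j)) (1/2)^f ... (own-type birth weight),
    c = 1 − σ_(i,j;f)          (death weight),

whose linear coefficient collects the already-known `Q`s of all recombinant
and unlinked-loss targets, weighted by `binom(f, g) (1/2)^f` for unlinked
transmission.  The relevant solution is always the smaller root.  To avoid
cancellation when the smaller root is near 0, the larger root is computed
first from the stable sign combination and the smaller obtained from the
product of roots (Vieta).  Closed forms for the all-unlinked (`Q_f`) and
single-linked (`Q_(0,1)`) cases are implemented as independent cross-checks;
at `r = 1/2` the single-linked case reduces exactly to the unlinked one.

The introgression probability is `1 − Q` of the founder class.

A class is *supercritical* when `σ − r > 0` strictly; only supercritical
classes can found a permanent lineage of their own type.  Conditional on
non-extinction, the probability that class `(i, j)` is the *rescue type* (the
first type to found an immortal own-type lineage, with no such founder among
its ancestors) follows a recursion with base case: a supercritical founder is
its own rescue type with conditional probability 1 after refinement by the
own-type establishment probability `(σ − r)/(1 − r)` relative to overall
survival `1 − Q`.  Subcritical classes distribute their mass over their
recombination and unlinked-loss targets proportionally to the targets'
establishment weights.  The distribution sums to one by construction, and the
implementation asserts it to 1e−10.

## Deterministic phase: surviving the sweep

Once a haplotype establishes, it sweeps logistically from an effective
initial frequency `ν̄/N`, where `ν̄ = 1/p_est = (1 − r)/(σ − r)` corrects for
the conditioned fast early growth of a surviving lineage.  During the sweep,
recombination keeps producing fitter "escape" haplotypes (e.g. the clean
`(0,0)` type) at rate proportional to the sweeping frequency times the
wildtype frequency; an escape arising at time `t` establishes with a
time-dependent probability interpolating between its absolute advantage early
and its relative advantage `σ_target − σ_est` late.  For a single escape
target this double integral has a closed form (a power expression in the
logistic variables), evaluated between the frequencies `ν̄/N` and
`1 − ν̄/N`; the large-`N` limit (starting frequency → 0) is also provided
and the two agree to `O(ν̄/N)`.  For several targets acting independently the
retention probability is the product of the single-target factors, skipping
targets that are not supercritical in the swept background.

When escape classes can themselves be displaced (several classes of positive
fitness — competing escape pathways), no product form applies and a
Monte-Carlo estimator is used: escape times are drawn from the
time-inhomogeneous Poisson intensity by inversion of a trapezoid cumulative
integral with an analytic constant-background tail, each accepted escape
restarts the replicator dynamics for the new leader (up to 64 epochs), and
the fittest established class wins.  The estimator reports binomial standard
errors and is validated against the closed form where both apply.

## Pipeline

The fixation distribution concatenates the phases: the rescue-type
distribution gives which class establishes; the deterministic-phase retention
(closed-form when a single escape chain applies, Monte-Carlo otherwise) gives
which class ultimately fixes given the established one.  Conditional and
unconditional (multiplied by the introgression probability) distributions are
reported, together with the method used per row.  `quick_estimates` exposes
the standard back-of-envelope rules (tight-linkage rescue weights
`σ_01/(σ_00 + σ_01)`, chain weights, the reduction factor for a lethal outer
allele, and the recombination threshold below which a second allele matters).

## Moran simulator (oracle)

The exact individual-based simulator tracks genotypes as 64-bit masks (bit 0
the beneficial allele, then the left block, right block, and unlinked block)
and runs the full Moran event loop under numba.  It requires an additively
consistent fitness table and an interval-consistent recombination scheme,
because per-individual genotypes (not classes) recombine; both conditions are
validated and violated scenarios are rejected.

Two performance devices keep `N = 10^4` tractable:

* **No-op skipping.**  Events in which parent(s) and victim are all wildtype
  change nothing.  The eight (parent1, parent2, victim) carrier/wildtype
  combinations are enumerated, the all-wildtype one removed, and the event
  type drawn from the renormalized probabilities, advancing only effective
  events.
* **Establishment mode.**  For comparisons against branching-process
  quantities the run stops once carriers reach `stop_fraction · N`
  (establishment is then certain up to `O(1/N)` corrections), instead of
  simulating to fixation.

Death is fitness-weighted with weight `count · (1 − σ)` per class.  Random
numbers come from splitmix64; each replicate's stream is derived by
avalanche-mixing the (seed, replicate) pair through the finalizer, so streams
are independent (a raw additive offset would alias the generator's own
increment and correlate replicates).

The simulator is the ground truth: the test-suite compares it against the
extinction recursion, the rescue distribution, the closed-form retention, and
the full pipeline at fixed seeds within 3 binomial standard errors, and it is
itself validated against the exactly solvable single-class embedded chain,
whose down/up ratio per step is exactly `1 − σ` independent of `N`, giving
`P(fix) = σ / (1 − (1 − σ)^N)`.

## Numerical choices

* Quadratics are solved with the Vieta-stabilized smaller root (see above);
  the recursion reproduces a fixed-point iteration oracle to ~5e−11.
* The deterministic-phase closed form is evaluated in log space where the
  exponents are large; the `O(s²)` consistency of splitting one allele into
  two of half effect is part of the acceptance suite.
* Monte-Carlo routines take explicit integer seeds in `[0, 2^31)`; all CLI
  commands either require a seed or print the one they generated.

## Limitations

* Haploid selection only; no dominance, no diploid phase, no population
  structure or continued migration — a single migrant haplotype.
* Equal per-allele effects for the *unlinked* block (the class description
  `(i, j; f)` does not distinguish which unlinked alleles remain); linked
  effects are arbitrary.
* The branching approximation requires `N σ ≫ 1` and rare carriers; the
  deterministic-phase formulas additionally assume `ν̄ < N/2` and a
  displacing escape hierarchy (a target fitter than wildtype but less fit
  than the sweeping type is rejected as undefined).
* The simulator covers additive, interval-consistent scenarios only; matrix
  recombination schemes with source-dependent rates have no individual-based
  counterpart here.
* Near-critical settings (`N(σ_a − σ_b)` of order 1 for two competing
  classes) are drift-dominated; analytic and simulated fixation distributions
  then agree only qualitatively, and the documentation makes no quantitative
  claim in that regime.
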