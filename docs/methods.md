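# Methods

## Data model and conventions

A *chronogram* is a rooted tree whose branch lengths are durations in Ma
(millions of years before present). Node ages are derived, not stored: the
age of a node is its branch-length path sum to any descendant leaf. The
package assumes extant tips (every leaf at age 0) and strict ordering — each
internal node strictly older than its children. Ties (parent−child age
difference ≤ 1e-9 Ma by default) are parse errors, because the downstream
constraint semantics rely on strict inequalities over continuous ages.

Ultrametricity is validated at parse time: within each node, all path sums
to descendant leaves must agree to a relative tolerance of 1e-6. Dating
software truncates printed branch lengths, so a `repair` mode assigns each
node the mean of its leaf path sums instead of rejecting; repair is never
silent — it must be requested. The standalone validator reports per-leaf
deviations against the *median* root-to-leaf depth, so a single perturbed
terminal branch implicates exactly that leaf rather than shifting the
consensus.

The datedist dialect is one newick string per line; one leading non-tree
line (e.g. a saved-point count) is tolerated and skipped. Trees may encode
ages either as branch lengths (assumed here) or as node labels; only the
branch-length reading is implemented.

*Crown* of a clade = MRCA of its leaf set; *stem* = parent of that MRCA (the
divergence from the sister lineage). Clade resolution is strict by default:
if the named leaf set is not monophyletic in a given sample the operation
fails loudly rather than silently annexing extra taxa; an opt-in fallback
returns the spanning MRCA. Topology is allowed to vary across samples for
this reason, although traces from a fixed-topology dating run never exercise
it.

## Burn-in, medians, HPD

Burn-in removes the first `floor(fraction × N)` saved points, `N` being the
count at parse time; the default fraction is 0.2. Floor is used so a
fractional sample is never over-discarded. A trace remembers that burn-in
was applied and refuses a second application unless forced.

The 95% HPD is the standard shortest-window empirical estimator: with `n`
sorted ages and `k = ceil(level·n)`, scan all `n−k+1` windows of consecutive
order statistics and return the narrowest, breaking ties toward the lowest
lower bound. Known properties worth stating:

* it is exact against exhaustive search by construction (verified against an
  independent brute force in the tests);
* width is non-decreasing in the level;
* at small `n` the minimum-width selection is biased slightly *short* (it
  covers ≈92% of true mass at n=100 for a normal sample, ≈95% by n=2000).
  Coverage checks in the tests are therefore run at n=2000.

Medians are the usual sample median (mean of central order statistics for
even n). Reports round to whole Ma for display only; computation is full
precision.

## HGT constraints and conditional post-sampling

A transfer constraint requires `age(donor node) > age(recipient node)`,
strictly; exact equality counts as unsatisfied (it indicates degenerate
input, not evidence). Defaults for mapping transfers to nodes:

* **donor = donor clade's crown.** A transfer "from within" a clade happened
  on or after that clade's crown radiation, so crown-donor-older is the
  weakest constraint no placement of the true donor branch can violate. The
  actual donor branch, if known, can be targeted by overriding the selector
  or supplying a narrower clade.
* **recipient = recipient clade's crown.** A transfer into a stem lineage
  must predate the recipient's crown.

Filtering a trace on a constraint set keeps exactly the samples satisfying
*all* constraints (logical AND), preserving order. The acceptance rate is
relative to the post-burn-in count; burn-in before filtering is the default
and skipping it warns. Zero survivors is a warning, not an error, so model
sweeps can continue past an infeasible configuration. Filtering is by
construction idempotent and composes as set intersection — both are enforced
as tests.

Transfer-feasibility probabilities `P(age A > age B)` are computed on the
same trace the model defines (for a constrained model, the filtered trace).
Paired mode (default) walks two age traces in lockstep, appropriate when
both come from the same posterior samples; unpaired mode forms the
cross-product estimate for independent traces, computed in O(n log n) by
sorting. Ties are counted separately and excluded from the numerator, so
P(A>B) + P(B>A) + tie fraction = 1. Whether published feasibility values of
this kind were computed paired or marginal is generally not stated; paired
is the default here because it respects the joint posterior.

## Calibrations and the index-HGT prerequisite check

Calibration files follow the count-headed `taxonA taxonB upper lower`
dialect with `−1` as the "no bound" sentinel; *upper* is the maximum age and
*lower* the minimum age, attached to the crown MRCA of the pair. Bounds are
hard — no soft tails, no prior-density evaluation; a sample audit reports
every calibrated node outside its window. Root priors are flat (hard
bounds), gamma, or normal; only the flat shape generates hard violations.

The mechanical index-HGT check evaluates the calibration prerequisite: it
warns when neither donor nor recipient crown contains a calibrated node and
informs when only the donor side is calibrated (recipient-side is
preferable because the constraint acts on the recipient crown). The two
gene-tree prerequisites — resolved donor placement, species-tree congruence
— cannot be evaluated from calibration tables and are emitted as fixed
notices so reports always show they were *assumed*, not checked.

## The calibrated-prior sampler

`sample_prior` emulates dating "under the prior" on a fixed topology. The
stationary density: root age from the root prior; conditional on the root,
uncalibrated internal node ages uniform subject to parent-older-than-child;
hard calibration bounds as indicators. The phrase "normally distributed
gamma root prior" that circulates for these analyses conflates two families;
here it is implemented as a gamma matched by mean m and SD s (shape m²/s²,
scale s²/m), which keeps ages positive; a pure normal is selectable.

The sampler sweeps internal nodes in random order. Every non-root node has
an exact uniform conditional — its age is uniform on
`(max(child ages, min bound), min(parent age, max bound))` — so it is drawn
directly (a Gibbs update). The root uses a Gaussian random-walk Metropolis
step with proposal SD equal to the prior SD, accepted against the root
density times the ordering/bound indicators; under a flat root prior the
root conditional is itself uniform and is drawn exactly. Infeasible bound
combinations are detected before sampling by interval propagation (minimum
ages pushed rootward, maximum ages pushed tipward; any crossing aborts).
The first 10% of sweeps are discarded and every thin-th sweep is emitted.
No birth-death process is modelled — uniform-given-root is the simplest
prior consistent with the intended use, and the sampler is a test harness,
not a reproduction of any dating program's internal joint prior.

## The jitter generator (pseudo-posterior traces)

`simulate_posterior_trace` redraws node ages root-down from normals centered
on a true chronogram's ages, truncated to `(0, parent age)`, so ordering and
positivity hold in every sample by construction. It returns both the trace
and a truth ledger — the exact per-sample, per-node ages as a DataFrame —
which downstream tests use as an oracle that never touches the tree-parsing
path (e.g. filter acceptance rates must equal ledger-computed fractions
*exactly*). Internal nodes are keyed `anc_<smallest leaf>_<leaf count>`,
which is provably unique on any topology.

What the generator emulates: a fixed topology, sample-to-sample jitter of
node ages, hard ordering. What it does not: posterior correlation structure
between nodes beyond the parent-child truncation, rate variation,
calibration-shaped marginals, topological uncertainty. Passing tests on
jittered traces therefore validate the *mechanics* (parsing, resolution,
filtering, summarization) — they say nothing about the statistical behavior
of any particular dating model on real data. Truncation also shifts
per-node means slightly away from the truth (upward at nodes squeezed by a
young parent), which recovery tests allow for.

The bundled 15-leaf tree (`synthetic_truth.nwk`) is a constructed stand-in,
not a published phylogeny: a plausible deep-bacterial shape with a 3900 Ma
root in which crown Chloroflexi (3200 Ma) predates the
Cyanobacteria/Melainabacteria ancestor (2800 Ma) and crown GNS (1900 Ma)
predates crown GSB (1750 Ma), so both bundled transfer constraints hold in
truth and jittered traces satisfy them in an informative, noise-dependent
fraction of samples.

## Model presets and comparisons

Presets bundle the root priors of the model families this toolkit targets:
phototroph models A–D (gamma root, mean 3900 Ma, SD 200 Ma; A no
constraints, B SahH, C BchH, D both), three Gloeobacter-outgroup models
(flat 3800–2450 Ma, flat 2700–2320 Ma, normal 2500±200 Ma) and four
Alphaproteobacteria-outgroup models (flat 3800–2400 Ma), each with its
akinete-calibration (1.2 or 1.6 Ga minimum) and GOE-placement flags. Taxon
scopes are recorded as documentation notes only — enforcing them would
require the original taxon lists.

`compare_models` reports per-clade median shifts (Ma) and HPD-width
reductions, `100·(1 − w_constrained/w_unconstrained)` — negative when an
interval widened, 100% for a zero-width constrained interval, undefined
(error) when the unconstrained width is zero. The bundled
`phototroph_model_summaries.tsv` carries published median/HPD endpoints for
models A and D under both akinete settings; arithmetic on its stem-GNS rows
yields width reductions of 53.6% (1.2 Ga) and 83.9% (1.6 Ga), the
constraint-driven precision gain the acceptance script recomputes. Rows
loaded from that table carry a placeholder sample count of 1 (the underlying
MCMC sample sizes are not published with the endpoints).

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make Monte-Carlo assertions
sharp at interactive cost: 500 mixed-distribution vectors (n ≤ 200) for the
HPD-vs-brute-force identity; 10⁵ draws for the closed-form ordering
probability, compared within 3 projection-estimated standard errors; 50
jittered traces of 30 samples for exact filter-rate agreement; 2×10⁴ prior
samples for root recovery (mean within 2%, SD within 5%). Assertions on
stochastic quantities always use explicit seeds and standard-error-based
tolerances rather than hand-picked margins.

Known limitations: no serially-sampled (non-extant) tips; no branch-rate or
convergence diagnostics; no NEXUS translate-table input; HGT constraints
are hard (no probabilistic weighting); the prior sampler is a testing
stand-in, not a replica of any dating program's effective joint prior.
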