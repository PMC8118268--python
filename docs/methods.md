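# Methods

## Model

`pbdelim` treats speciation as a protracted process: restrictions in gene
flow create isolated *population lineages* long before those lineages are
distinct species, and a lineage only acquires full species status when a
*speciation-completion event* occurs on its branch.  The data are a rooted
lineage tree `S` with strictly positive branch durations (typically a
population tree estimated under the multispecies coalescent; that upstream
inference is out of scope here).  A delimitation hypothesis is a set
partition Λ of the tips into species: two tips are conspecific exactly when
no branch on the path between them carries a completion event.

Completion events on a branch of duration τ are Poisson with mean στ, where
σ is the speciation-completion rate (events per lineage per time; its units
are the reciprocal of the branch-duration units).  Only the distinction
between 0 and ≥ 1 events matters, so per branch

    Pr(no event) = exp(-στ),   Pr(≥1 event) = 1 - exp(-στ),

independently across branches.  The likelihood of a partition is

    L = Pr(Λ | σ, S) = Σ_configs compatible with Λ  Π_i f_i(σ, τ_i),

where a configuration assigns event/no-event to every branch and is
compatible with Λ when its event-free connected components induce exactly
the blocks of Λ.

## Partition likelihood by pruning

Direct summation costs 2^(#branches).  `partition_probability` instead runs
a dynamic program over a postorder traversal.  At each node the state of the
"open" component — the event-free component containing that node — is either
EMPTY (holds no leaves) or one block `b` of Λ, meaning the component holds
exactly the leaves of `b` visited so far, with all other visited leaves
sealed inside completed blocks.  A child edge contributes either an event
factor 1 − e^(−στ) — legal only if the child's open state is EMPTY or a
block wholly contained in the child's subtree, which the event completes —
or a no-event factor e^(−στ), which propagates the child's open state.
Sibling states merge by EMPTY ∘ s = s, b ∘ b = b, and b ∘ b′ infeasible
(dropped).  At the root, states EMPTY and any (necessarily complete) open
block are summed; there is no branch above the root.  The run time is linear
in node count per partition, polytomies are handled by folding children in
left to right (the merge is associative), and all accumulation is in log
space (`log1p`/`expm1` guards near στ → 0 and large στ; exponentiated
probabilities are clamped to [0, 1]).  The scheme was derived from the
connectivity semantics above and is validated against the exhaustive
2^branches oracle (`partition_probability_bruteforce`) rather than against
any reference implementation.

A partition has probability zero exactly when the minimal connecting
subtrees of its blocks share a vertex; the test suite checks this against an
independent shortest-path graph oracle.

## Ranking, credibility sets, conspecificity

Candidate partitions are every partition of the leaf set compatible with the
constraints: constrained species act as pre-merged atoms that may not merge
with each other, and each unknown tip joins an existing species or groups
with other unknowns.  Enumeration follows restricted-growth strings with
species atoms placed first (deterministic order; ties in probability are
broken by the canonical partition order, blocks sorted by smallest label).
Conditional probabilities normalize over this candidate set, and the 95%
credibility set is the smallest prefix of the ranking whose cumulative
conditional probability reaches 0.95.  The probability that a target set of
tips is conspecific is the sum of conditional probabilities of candidates
grouping them together.

Enumeration is refused above a configurable cap (default 2×10⁷ candidates)
because the candidate count grows as a (generalized) Bell number: Bell(15)
≈ 1.4×10⁹ is already out of reach of desk-scale memory.  The count is
computed in closed recurrence *before* any enumeration, so the refusal is
instant and names the count.

With a posterior sample of trees over one leaf set, unconditional partition
probabilities are arithmetically averaged across trees before
normalization.

## Rate estimation

With species identities of all tips of interest given (the "tempo" mode, or
stage one of the constrained mode applied to the induced tree on the
constrained tips), the log-likelihood of σ is log Pr(Λ | σ, S).  Two
boundary cases are exact: a single-block partition gives σ̂ = 0 (the
likelihood e^(−σ·total length) is maximized at zero) and an all-singletons
partition gives σ̂ = ∞; both are returned as flagged results, not errors.
Otherwise the likelihood vanishes at both extremes and an interior maximum
exists; it is found by bounded scalar minimization on log σ over
[10⁻⁸, 10³] × (1 / mean branch duration) with tolerance 10⁻⁸ in log σ.

Confidence intervals use observed Fisher information: the negated central
second difference of the log-likelihood at σ̂ with step h = max(10⁻⁶,
10⁻⁴ σ̂), SE = I^(−1/2), interval σ̂ ± z₀.₉₇₅·SE truncated below at zero.
Non-positive curvature yields an explicit "undefined CI" flag.  Expected
(rather than observed) information would require integrating over data sets
and is not used.

Constrained delimitation is sequential, not joint: σ̂ is estimated from the
induced tree on the constrained tips (assumed a random subset of the
leaves), then every compatible partition of the full tree is ranked at σ̂.
No σ-uncertainty is propagated into the partition probabilities; the
ranking conditions on the point estimate.

## Simulator

`simulate_dataset` runs a Gillespie simulation of the protracted
birth–death process: every extant lineage splits at rate b and dies at rate
μ, and every *incipient* lineage completes speciation at rate σ, becoming a
full species.  A newly budded lineage starts incipient and inherits its
parent's species identity until its own completion.  The distinct
good/incipient splitting and extinction rates of the full
protracted-birth-death literature are collapsed to single b and μ, matching
the validation study design (b = 0.1, μ = 0).  The process starts from a
single full-species lineage with no stem branch above the root, so a binary
n-tip tree has 2n − 2 branches.

Stopping rule: the run stops the first time the extant count reaches
`n_tips`; tip branches are then extended by Uniform(0, W), where W is the
next Gillespie waiting time.  Stopping exactly at the last split would
leave two zero-duration pendant branches, violating the tree invariants;
the uniform extension keeps all durations positive and the tree exactly
ultrametric.  Runs that go fully extinct first are redrawn (up to 100
times).  Extinct subtrees are pruned and unifurcations suppressed with
durations summed.  Surviving completion events are mapped onto the pruned
branches, and the true partition (tips grouped by final species identity)
always equals the event-free connectivity of that configuration — an
invariant the test suite checks, since it is what makes the simulator's
truth commensurable with the likelihood model.

`paint_completion_events` is the *model-exact* alternative generator:
independent Poisson(στ) counts on every branch of an existing tree.
Painting after pruning is equivalent to marking during growth because the
Poisson marks are independent of the branching process.  It differs from
the full process in one respect: painted events can fall on any branch,
whereas the forward process places them only on still-incipient lineages
(at most one completion per lineage).  The full process therefore produces
slightly fewer, differently placed species — at 15 tips with b = 0.1 and σ
spanning 0.01–0.1 the mean species count is ≈ 4.9–5.1 under the forward
process versus ≈ 5.9 under painting.  The forward process is the
data-generating model of the validation studies (and matches dendropy's
`ProtractedSpeciationProcess`, against which the simulator is cross-checked
in the test suite); painting is used where model-exact data is wanted, e.g.
for checking the nominal coverage of the Fisher intervals.

What the simulator does *not* emulate about real data: lineage trees are
generated without estimation error (real trees come from MSC inference with
their own uncertainty), branch durations are exactly ultrametric, the
completion rate is constant across lineages and time, and constrained tips
are hidden uniformly at random rather than by the biased designs of real
taxonomic sampling.  Passing benchmarks therefore demonstrate correctness
and statistical behaviour of the method under its own generating model, not
robustness to tree error or ascertainment bias.

## Benchmark and acceptance problem sizes

The shipped benchmarks are desk-scale replicas of the validation studies:
tens of replicates at 8–15 tips for modes that enumerate all Bell(n)
partitions, and 50–100 replicates at 60 tips for rate estimation (one DP
evaluation is linear in tree size, so only enumeration limits scale).  The
published full-scale design — 15-tip unconstrained runs against
Bell(15) ≈ 1.4×10⁹ candidates, and 80-tip constrained grids — requires
cluster-scale memory and is deliberately not reproduced.

`scripts/acceptance.py --seed N --out results.json` regenerates the two
simulation study designs (15-tip, rates 0.01–0.1, 100 replicates per rate;
60-tip, nine rates 0.001–0.1, 100 replicates per rate) and writes the
species-count moments.

## Known limitations

- Joint inference of tree and σ is not attempted; the two-stage constrained
  mode inherits whatever bias the constrained-subset induced tree carries.
- The likelihood model treats branches independently, while the forward
  process completes each lineage at most once; at high σ this mismatch (and
  saturation — extra events on an already-cut path change nothing) biases
  σ̂ downward, visible in the tempo benchmark at σ near b.
- No heuristic search over partition space: above the enumeration cap the
  package refuses rather than approximates.
- Newick input only; trees must be rooted with every branch length present
  and positive (no repair is attempted).
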