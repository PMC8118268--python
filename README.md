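# pbdelim

Species delimitation on population-lineage trees under a protracted
speciation model.

Genomic species-delimitation methods built directly on the multispecies
coalescent conflate population structure with species boundaries: any
detectable restriction in gene flow is promoted to a species.  `pbdelim`
separates the two processes.  Tips of the input tree are *population
lineages* (e.g. from a BP&P or \*BEAST analysis); a lineage only becomes a
distinct species once a *speciation-completion event* has occurred on a
branch separating it from its relatives.  Completion events on a branch of
duration τ are Poisson with mean στ, so the probability that a branch stays
event-free is e^(−στ).  A delimitation hypothesis is a set partition Λ of
the tips, and its likelihood given the tree S and completion rate σ,

&nbsp;&nbsp;&nbsp;&nbsp;L = Pr(Λ | σ, S),

sums the probabilities of all per-branch event configurations whose
event-free connectivity induces exactly Λ — computed by a pruning-style
dynamic program rather than by 2^(#branches) enumeration.

The package supports three modes of inference:

- **constrained** — species identities of *some* tips are known; σ is
  estimated by maximum likelihood from the tree induced by those tips, then
  every partition compatible with the constraints is ranked at σ̂, giving a
  MAP delimitation and a 95% credibility set;
- **unconstrained** — no identities known; all Bell(n) partitions are
  ranked at a user-supplied σ;
- **tempo of speciation** — all identities known; only σ (with a
  Fisher-information confidence interval) is estimated.

A forward Gillespie simulator of the protracted birth–death process
(isolation rate b, extinction rate μ, completion rate σ) generates trees
with known true species for validation, and `pbdelim.benchmark` replays
scaled-down versions of the method's published validation studies.
See `docs/methods.md` for the model, algorithms, and limitations.

## Worked example

```python
import pbdelim as pb

# simulate a 10-tip tree: populations isolate at rate 0.1, complete
# speciation at rate 0.02 (five times slower), no extinction
ds = pb.simulate_dataset(
    pb.PBDParams(isolation_rate=0.1, completion_rate=0.02), 10, seed=42
)
print("truth:", ds.partition)

# pretend the identities of the last three tips are unknown
names = ds.partition.names
known = {l: names[ds.partition.block_of(l)]
         for l in sorted(ds.tree.leaf_label_set)[:-3]}
res = pb.DelimitationModel(ds.tree, pb.ConstraintSet(known)).fit()
print(res.summary(max_rows=5))
```

Output:

```
truth: SpeciesPartition(L0,L4,L5,L7,L8; L1,L6; L2,L3,L9)
Species delimitation
====================
candidate partitions:  77
sigma used:            0.0233414  (estimated from constraints)
credibility set size:  3 (level 0.95)

 rank  n_species  conditional_probability  cumulative_conditional_probability                     partition
    1          3                 0.834191                            0.834191 L0,L4,L5,L7,L8;L1,L6;L2,L3,L9
    2          4                0.0744861                            0.908677 L0,L4,L5,L8;L1,L6;L2,L3,L9;L7
    3          4                0.0534943                            0.962172 L0,L4,L5,L7;L1,L6;L2,L3,L9;L8
    4          4                0.0285138                            0.990686 L0,L4,L5,L7,L8;L1,L6;L2,L3;L9
    5          5               0.00477659                            0.995462 L0,L4,L5;L1,L6;L2,L3,L9;L7;L8
... (72 further partitions)

Speciation-completion rate estimate
===================================
tips:                  7
species (blocks):      3
sigma_hat:             0.0233414
log-likelihood:        -6.3288
95% CI (fisher):       [0, 0.0557081]
completion time 1/s:   42.8424
```

The completion rate estimated from the seven constrained tips (σ̂ ≈ 0.023,
true value 0.02) drives the ranking of the 77 constraint-compatible
partitions of all ten tips.  The highest-probability partition assigns the
three unknown tips to their true species (conditional probability 0.83),
and the 95% credibility set needs only the top three partitions.  The
estimated waiting time for an isolated lineage to complete speciation is
1/σ̂ ≈ 43 time units.

The same analyses are available from the shell:

```sh
pbdelim simulate --tips 10 --isolation-rate 0.1 --completion-rate 0.02 \
    --seed 42 --output-prefix rep0
pbdelim delimit --tree rep0.nwk --constraints constraints.tsv -o result.json
pbdelim estimate-rate --tree rep0.nwk --constraints full_assignments.tsv
```

Constraint tables are TSV (`lineage  species  status`; status 1 =
known, 0 = unknown).  Multi-tree Newick input (a posterior sample) averages
partition probabilities across trees.

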