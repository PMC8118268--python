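"""Probability of a species partition given a lineage tree and completion rate.

The number of speciation-completion events on a branch of duration ``tau`` is
Poisson with mean ``sigma * tau``, independently across branches, and only
the distinction between 0 and >= 1 events matters: a partition is induced by
an event configuration through event-free connectivity.  The probability of a
partition is therefore the sum, over all configurations inducing it, of

    prod_i  exp(-sigma * tau_i)            (branch i event-free)
            1 - exp(-sigma * tau_i)        (branch i carries >= 1 events)

Summing configurations directly costs 2^(#branches); ``partition_probability``
instead runs a pruning-style dynamic program over a postorder traversal,
linear in node count, with ``partition_probability_bruteforce`` retained as
the exhaustive oracle for small trees.

State scheme of the dynamic program: at each node the "open" component (the
connected event-free component containing the node) either holds no leaves
(state EMPTY) or exactly the so-far-visited leaves of one block b of the
partition, with every other leaf in the subtree sealed inside completed
blocks.  A child edge either carries an event — legal only if the child's
open state is EMPTY or a block lying entirely inside the child's subtree,
which the cut completes — or no event, in which case the child's open state
propagates.  Sibling open states merge as EMPTY o s = s, b o b = b, and
b o b' infeasible.  All accumulation is in log space.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import ConfigurationDomainError, InputError
from .partition import (
    DEFAULT_PARTITION_CAP,
    ConstraintSet,
    EventConfiguration,
    SpeciesPartition,
    enumerate_compatible_partitions,
    induced_partition,
    is_compatible,
)
from .tree import LineageTree

__all__ = [
    "PartitionScore",
    "RankedPartitionTable",
    "branch_no_event_probability",
    "configuration_probability",
    "partition_probability",
    "partition_probability_bruteforce",
    "partition_log_probability",
    "rank_partitions",
    "conspecificity_probability",
]

_EMPTY = -1  # open-state marker: component holds no leaves
_NEG_INF = float("-inf")


def _logaddexp(a: float, b: float) -> float:
    """Scalar log(exp(a) + exp(b)); faster than the ufunc in the DP loop."""
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    d = a - b
    if d >= 0.0:
        return a + math.log1p(math.exp(-d))
    return b + math.log1p(math.exp(d))


def _log1mexp(x: float) -> float:
    """log(1 - exp(-x)) for x >= 0, stable near both ends."""
    if x <= 0.0:
        return _NEG_INF
    if x < 0.6931471805599453:  # ln 2
        return math.log(-math.expm1(-x))
    return math.log1p(-math.exp(-x))


def branch_no_event_probability(sigma: float, tau: float) -> float:
    """Probability of zero completion events on a branch: exp(-sigma*tau)."""
    if sigma < 0:
        raise InputError(f"negative completion rate {sigma}")
    if tau <= 0:
        raise InputError(f"non-positive branch duration {tau}")
    return math.exp(-sigma * tau)


def configuration_probability(
    tree: LineageTree, config: EventConfiguration, sigma: float
) -> float:
    """Probability of one event configuration (product over branches)."""
    if config.tree is not tree:
        raise ConfigurationDomainError("configuration bound to a different tree")
    if sigma < 0:
        raise InputError(f"negative completion rate {sigma}")
    st = sigma * tree.branch_lengths
    logp = 0.0
    for x, has_event in zip(st, config.events):
        logp += _log1mexp(x) if has_event else -x
    return math.exp(logp) if logp > _NEG_INF else 0.0


@dataclass(frozen=True)
class PartitionScore:
    """A partition with its (log-)probability under a fixed rate."""

    partition: SpeciesPartition
    log_probability: float

    @property
    def probability(self) -> float:
        if self.log_probability == _NEG_INF:
            return 0.0
        return min(1.0, math.exp(self.log_probability))


def _check_partition(tree: LineageTree, partition: SpeciesPartition) -> None:
    if partition.labels != tree.leaf_label_set:
        raise InputError(
            "partition does not cover exactly the tree's leaf set"
        )


def partition_log_probability(
    tree: LineageTree, partition: SpeciesPartition, sigma: float
) -> float:
    """Natural log of Pr(partition | sigma, tree), by the pruning DP.

    Returns ``-inf`` for partitions of probability zero (blocks whose minimal
    connecting subtrees are not vertex-disjoint, or any multi-tip split when
    ``sigma == 0``).
    """
    _check_partition(tree, partition)
    if sigma < 0:
        raise InputError(f"negative completion rate {sigma}")

    block_of = {label: partition.block_of(label) for label in partition.labels}
    block_sizes = [len(b) for b in partition.blocks]

    # per-node: open-state -> accumulated log-probability
    states: dict = {}
    # per-node: number of leaves of each block seen in its subtree
    seen: dict = {}

    for node in tree.postorder_nodes():
        if node.is_leaf():
            b = block_of[node.taxon.label]
            states[node] = {b: 0.0}
            seen[node] = {b: 1}
            continue
        counts: dict = {}
        acc = {_EMPTY: 0.0}
        for child in node.child_nodes():
            for b, c in seen[child].items():
                counts[b] = counts.get(b, 0) + c
            tau = child.edge.length
            log_p0 = -sigma * tau
            log_p1 = _log1mexp(sigma * tau)
            child_states = states.pop(child)
            child_seen = seen[child]
            # options this child edge contributes to the parent
            opts: dict = {}
            for s, lp in child_states.items():
                v = lp + log_p0  # no event: open state propagates
                if s in opts:
                    opts[s] = _logaddexp(opts[s], v)
                else:
                    opts[s] = v
                if log_p1 > _NEG_INF and (
                    s == _EMPTY or child_seen.get(s, 0) == block_sizes[s]
                ):
                    # event: seals the child's open component, which must be
                    # a complete block (or hold no leaves)
                    v = lp + log_p1
                    if _EMPTY in opts:
                        opts[_EMPTY] = _logaddexp(opts[_EMPTY], v)
                    else:
                        opts[_EMPTY] = v
            new_acc: dict = {}
            for s1, lp1 in acc.items():
                for s2, lp2 in opts.items():
                    if s1 == _EMPTY:
                        s = s2
                    elif s2 == _EMPTY or s1 == s2:
                        s = s1
                    else:
                        continue  # two different open blocks cannot merge
                    v = lp1 + lp2
                    if s in new_acc:
                        new_acc[s] = _logaddexp(new_acc[s], v)
                    else:
                        new_acc[s] = v
            acc = new_acc
            if not acc:
                return _NEG_INF
        states[node] = acc
        seen[node] = counts

    root_states = states[tree.root]
    # at the root every leaf has been visited, so any open block is complete
    # and is closed by default (no branch above the root)
    vals = [v for v in root_states.values() if v > _NEG_INF]
    if not vals:
        return _NEG_INF
    return float(logsumexp(vals))


def partition_probability(
    tree: LineageTree, partition: SpeciesPartition, sigma: float
) -> PartitionScore:
    """Pr(partition | sigma, tree) via the pruning dynamic program."""
    return PartitionScore(partition, partition_log_probability(tree, partition, sigma))


def partition_probability_bruteforce(
    tree: LineageTree, partition: SpeciesPartition, sigma: float
) -> PartitionScore:
    """Exhaustive oracle: sum over all 2^(#branches) event configurations.

    Intended for trees with at most ~12 branches.
    """
    _check_partition(tree, partition)
    if sigma < 0:
        raise InputError(f"negative completion rate {sigma}")
    n = tree.n_branches
    total = 0.0
    for bits in itertools.product((0, 1), repeat=n):
        config = EventConfiguration(tree, bits)
        if induced_partition(tree, config) == partition:
            total += configuration_probability(tree, config, sigma)
    logp = math.log(total) if total > 0 else _NEG_INF
    return PartitionScore(partition, logp)


@dataclass
class RankedPartitionTable:
    """Candidate partitions ranked by probability at a fixed rate.

    ``conditional_probability`` normalizes over the constraint-compatible
    candidate set; the 95% credibility set is the smallest prefix of the
    ranking whose cumulative conditional probability reaches the level.
    """

    sigma: float
    partitions: list = field(repr=False)
    log_probabilities: np.ndarray = field(repr=False)
    conditional_probabilities: np.ndarray = field(repr=False)
    credibility_level: float = 0.95

    def __post_init__(self):
        self.log_probabilities = np.asarray(self.log_probabilities, float)
        self.conditional_probabilities = np.asarray(
            self.conditional_probabilities, float
        )
        self.cumulative = np.cumsum(self.conditional_probabilities)
        k = int(np.searchsorted(self.cumulative, self.credibility_level) + 1)
        self.credibility_set_size = min(k, len(self.partitions))

    def __len__(self) -> int:
        return len(self.partitions)

    @property
    def map_partition(self) -> SpeciesPartition:
        return self.partitions[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Unconditional probabilities Pr(partition | sigma, tree)."""
        with np.errstate(under="ignore"):
            return np.minimum(1.0, np.exp(self.log_probabilities))

    def in_credibility_set(self, partition: SpeciesPartition) -> bool:
        for i in range(self.credibility_set_size):
            if self.partitions[i] == partition:
                return True
        return False

    def rank_of(self, partition: SpeciesPartition) -> Optional[int]:
        """0-based rank, or None if the partition is not a candidate."""
        for i, p in enumerate(self.partitions):
            if p == partition:
                return i
        return None

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.partitions):
            rows.append(
                {
                    "rank": i + 1,
                    "n_species": p.n_species,
                    "partition": ";".join(",".join(b) for b in p.blocks),
                    "log_probability": self.log_probabilities[i],
                    "probability": self.probabilities[i],
                    "conditional_probability": self.conditional_probabilities[i],
                    "cumulative_conditional_probability": self.cumulative[i],
                    "in_credibility_set": i < self.credibility_set_size,
                }
            )
        return pd.DataFrame(rows)

    def to_records(self) -> list:
        records = []
        for i, p in enumerate(self.partitions):
            records.append(
                {
                    "species_partition": [list(b) for b in p.blocks],
                    "n_species": p.n_species,
                    "log_probability": (
                        _sig(self.log_probabilities[i])
                        if math.isfinite(self.log_probabilities[i])
                        else None
                    ),
                    "probability": _sig(self.probabilities[i]),
                    "conditional_probability": _sig(
                        self.conditional_probabilities[i]
                    ),
                    "cumulative_conditional_probability": _sig(self.cumulative[i]),
                    "in_credibility_set": bool(i < self.credibility_set_size),
                }
            )
        return records

    def to_json(self, path=None, **meta) -> str:
        payload = dict(meta)
        payload["sigma"] = self.sigma
        payload["credibility_level"] = self.credibility_level
        payload["partitions"] = self.to_records()
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        self.as_dataframe().to_csv(path, sep="\t", index=False)


def _sig(x: float, digits: int = 12) -> float:
    if not math.isfinite(x) or x == 0.0:
        return float(x)
    return float(f"{x:.{digits}g}")


def rank_partitions(
    tree: LineageTree,
    constraints: Optional[ConstraintSet] = None,
    sigma: float = 0.0,
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
    credibility_level: float = 0.95,
) -> RankedPartitionTable:
    """Score every constraint-compatible partition of the tree at ``sigma``.

    Conditional probabilities are normalized over the compatible set; rows
    are sorted by probability descending with ties broken by the canonical
    partition order.
    """
    constraints = constraints or ConstraintSet()
    constraints.validate_against(tree)
    parts = list(
        enumerate_compatible_partitions(tree.leaf_labels, constraints, cap=cap)
    )
    logps = np.array(
        [partition_log_probability(tree, p, sigma) for p in parts], float
    )
    return _build_table(parts, logps, sigma, credibility_level)


def _build_table(parts, logps, sigma, credibility_level=0.95):
    order = sorted(
        range(len(parts)), key=lambda i: (-logps[i], parts[i].sort_key())
    )
    parts = [parts[i] for i in order]
    logps = logps[order]
    norm = logsumexp(logps)
    if norm == _NEG_INF:
        raise InputError("every candidate partition has probability zero")
    with np.errstate(under="ignore"):
        cond = np.exp(logps - norm)
    cond /= cond.sum()
    return RankedPartitionTable(
        sigma=float(sigma),
        partitions=parts,
        log_probabilities=logps,
        conditional_probabilities=cond,
        credibility_level=credibility_level,
    )


def conspecificity_probability(
    tree: LineageTree,
    constraints: Optional[ConstraintSet],
    sigma: float,
    targets: Iterable[str],
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
) -> float:
    """Probability that all ``targets`` belong to one species.

    Integrates over the constraint-compatible partitions: the sum of the
    conditional probabilities of partitions grouping every target together.
    """
    targets = set(targets)
    if len(targets) < 2:
        raise InputError("need at least two target tips")
    unknown = targets - tree.leaf_label_set
    if unknown:
        raise InputError(f"targets not in tree: {sorted(unknown)}")
    table = rank_partitions(tree, constraints, sigma, cap=cap)
    total = 0.0
    for p, cp in zip(table.partitions, table.conditional_probabilities):
        if p.same_species(targets):
            total += float(cp)
    return min(1.0, total)
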