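"""Forward simulation of the protracted speciation process.

Population lineages split at the isolation rate ``b`` and die at the
extinction rate ``mu``; an *incipient* lineage (one that has not yet
completed speciation) completes at rate ``sigma``, at which point it becomes
a full species.  A newly budded lineage starts incipient and belongs to its
parent's species until its own completion event.  The simulation starts from
a single full-species lineage, stops the first time the extant lineage count
reaches the requested tip number (tip branches are extended by a uniform
fraction of the next Gillespie waiting time, so durations stay positive),
prunes extinct lineages, and suppresses the resulting unifurcations with
branch durations summed.

The returned dataset carries the pruned lineage tree, the surviving
completion events mapped onto its branches, and the true species partition;
the partition always equals the event-free connectivity of the event
configuration (checked property, not an assumption).

``paint_completion_events`` offers the alternative, likelihood-exact
generator: independent Poisson event counts on every branch of an existing
tree.  Painting after pruning is equivalent to marking events during growth
because the Poisson marks are independent of the branching process; it
differs from the full process above in that painted events are not
restricted to incipient lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .exceptions import InputError, PbdelimError
from .partition import EventConfiguration, SpeciesPartition
from .tree import LineageTree

logger = logging.getLogger(__name__)

__all__ = [
    "PBDParams",
    "SimulatedDataset",
    "simulate_lineage_tree",
    "paint_completion_events",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PBDParams:
    """Rates of the protracted speciation process (per lineage per time)."""

    isolation_rate: float  # b: new isolated population lineages
    extinction_rate: float = 0.0  # mu
    completion_rate: float = 0.0  # sigma

    def __post_init__(self):
        if not self.isolation_rate > 0:
            raise InputError("isolation rate must be positive")
        if self.extinction_rate < 0:
            raise InputError("extinction rate must be non-negative")
        if self.completion_rate < 0:
            raise InputError("completion rate must be non-negative")
        if self.extinction_rate >= self.isolation_rate:
            raise InputError(
                "extinction rate must be below the isolation rate for the "
                "process to reach the requested tip count"
            )

    def to_dict(self) -> dict:
        return {
            "isolation_rate": self.isolation_rate,
            "extinction_rate": self.extinction_rate,
            "completion_rate": self.completion_rate,
        }


class _Lineage:
    __slots__ = (
        "id",
        "parent",
        "origin",
        "species",
        "completion_time",
        "extinction_time",
        "incipient",
        "children",
    )

    def __init__(self, lid, parent, origin, species, incipient):
        self.id = lid
        self.parent = parent
        self.origin = origin
        self.species = species
        self.completion_time = None
        self.extinction_time = None
        self.incipient = incipient
        self.children = []


class _TotalExtinction(Exception):
    pass


def _gillespie(params: PBDParams, n_tips: int, rng: np.random.Generator):
    """One forward run; returns (lineages, extant, final_time)."""
    b, mu, sigma = (
        params.isolation_rate,
        params.extinction_rate,
        params.completion_rate,
    )
    root = _Lineage(0, None, 0.0, 0, incipient=False)
    lineages = [root]
    extant = [root]
    incipient: list = []
    next_species = 1
    t = 0.0
    while True:
        n = len(extant)
        if n == 0:
            raise _TotalExtinction()
        rate = n * (b + mu) + len(incipient) * sigma
        wait = rng.exponential(1.0 / rate)
        if n == n_tips:
            return lineages, extant, t + rng.uniform(0.0, wait)
        t += wait
        u = rng.uniform(0.0, rate)
        if u < n * b:
            parent = extant[min(int(u / b), n - 1)]
            child = _Lineage(len(lineages), parent, t, parent.species, True)
            parent.children.append(child)
            lineages.append(child)
            extant.append(child)
            incipient.append(child)
        elif mu > 0 and u < n * (b + mu):
            idx = min(int((u - n * b) / mu), n - 1)
            victim = extant[idx]
            victim.extinction_time = t
            extant[idx] = extant[-1]
            extant.pop()
            if victim.incipient:
                incipient.remove(victim)
        else:
            idx = min(int((u - n * (b + mu)) / sigma), len(incipient) - 1)
            lin = incipient[idx]
            lin.completion_time = t
            lin.species = next_species
            next_species += 1
            lin.incipient = False
            incipient[idx] = incipient[-1]
            incipient.pop()


def _build_pruned_tree(lineages, extant, final_time):
    """Binary pruned tree with per-branch lineage segments for event mapping."""
    extant_set = set(l.id for l in extant)
    survives: dict = {}
    for lin in reversed(lineages):  # children always follow parents
        survives[lin.id] = lin.id in extant_set or any(
            survives[c.id] for c in lin.children
        )
    if not survives[0]:
        raise _TotalExtinction()

    taxa = dendropy.TaxonNamespace()

    def build(lin, kid_idx, seg_start):
        kids = [c for c in lin.children if survives[c.id]]
        kids = kids[kid_idx:]
        if not kids:
            node = dendropy.Node()
            node.taxon = taxa.new_taxon(label=f"L{lin.id}")
            node.time = final_time
            node.segments = [(lin, seg_start, final_time)]
            return node
        child = kids[0]
        t0 = child.origin
        cont_survives = lin.id in extant_set or len(kids) > 1
        if not cont_survives:
            node = build(child, 0, t0)
            node.segments.append((lin, seg_start, t0))
            return node
        node = dendropy.Node()
        node.time = t0
        node.segments = [(lin, seg_start, t0)]
        all_kids = [c for c in lin.children if survives[c.id]]
        left = build(lin, all_kids.index(child) + 1, t0)
        right = build(child, 0, t0)
        for sub in (left, right):
            node.add_child(sub)
            sub.edge.length = sub.time - t0
        return node

    root = build(lineages[0], 0, 0.0)
    root.segments = []  # no stem branch above the root
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree


def simulate_lineage_tree(
    params: PBDParams,
    n_tips: int,
    seed=None,
    max_retries: int = 100,
) -> LineageTree:
    """Simulate a pruned, ultrametric lineage tree with ``n_tips`` leaves."""
    return simulate_dataset(params, n_tips, seed=seed, max_retries=max_retries).tree


def paint_completion_events(
    tree: LineageTree, sigma: float, seed=None
) -> EventConfiguration:
    """Draw independent Poisson(sigma * tau) completion-event counts on every
    branch of an existing tree (the generator the likelihood model assumes)."""
    if sigma < 0:
        raise InputError(f"negative completion rate {sigma}")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(sigma * tree.branch_lengths)
    return EventConfiguration(tree, (counts > 0).astype(np.int8), counts=counts)


@dataclass
class SimulatedDataset:
    """A simulated lineage tree with its true species identities."""

    tree: LineageTree
    config: EventConfiguration
    partition: SpeciesPartition
    params: PBDParams
    seed: object = None
    n_retries: int = 0

    @property
    def n_species(self) -> int:
        return self.partition.n_species

    def truth_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        names = self.partition.names or [
            f"sp{i + 1}" for i in range(self.partition.n_species)
        ]
        for i, block in enumerate(self.partition.blocks):
            for label in block:
                rows.append({"lineage": label, "species": names[i]})
        return pd.DataFrame(rows).sort_values("lineage", ignore_index=True)

    def metadata(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "seed": self.seed,
            "n_tips": self.tree.n_leaves,
            "n_species": self.n_species,
            "event_counts": {
                f"branch_{i}": int(c)
                for i, c in enumerate(self.config.counts)
                if c
            },
        }


def simulate_dataset(
    params: PBDParams,
    n_tips: int,
    seed=None,
    max_retries: int = 100,
) -> SimulatedDataset:
    """Simulate tree, completion events, and true species partition.

    The same ``(params, n_tips, seed)`` triple always reproduces the same
    dataset.  Runs in which the whole tree goes extinct before reaching
    ``n_tips`` are redrawn, up to ``max_retries``.
    """
    if n_tips < 2:
        raise InputError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries + 1):
        try:
            lineages, extant, final_time = _gillespie(params, n_tips, rng)
            dtree = _build_pruned_tree(lineages, extant, final_time)
            break
        except _TotalExtinction:
            continue
    else:
        raise PbdelimError(
            f"simulation went fully extinct {max_retries + 1} times; "
            "lower the extinction rate"
        )
    tree = LineageTree(dtree)

    # surviving completion events, mapped onto the pruned branches
    counts = np.zeros(tree.n_branches, dtype=int)
    for i, node in enumerate(tree.branches):
        for lin, a, b in node.segments:
            tc = lin.completion_time
            if tc is not None and a < tc <= b:
                counts[i] += 1
    config = EventConfiguration(
        tree, (counts > 0).astype(np.int8), counts=counts
    )

    # true species: group extant tips by final species identity
    by_species: dict = {}
    for lin in extant:
        by_species.setdefault(lin.species, []).append(f"L{lin.id}")
    blocks = sorted((tuple(sorted(v)) for v in by_species.values()),
                    key=lambda b: b[0])
    partition = SpeciesPartition(
        blocks, names=[f"sp{i + 1}" for i in range(len(blocks))]
    )
    return SimulatedDataset(
        tree=tree,
        config=config,
        partition=partition,
        params=params,
        seed=seed,
        n_retries=attempt,
    )
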