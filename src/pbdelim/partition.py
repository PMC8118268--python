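"""Species partitions, constraint sets, and completion-event configurations.

A species under the protracted speciation model is a set of population
lineages not separated from one another by any speciation-completion event,
so a delimitation hypothesis is a set partition of the tree's leaf labels.
Constraint sets record a-priori species identities for a subset of tips; an
event configuration records, per branch, whether at least one completion
event occurred on it.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

from .exceptions import (
    ConfigurationDomainError,
    ConstraintError,
    EnumerationCapError,
    InputError,
)
from .tree import LineageTree

__all__ = [
    "SpeciesPartition",
    "ConstraintSet",
    "EventConfiguration",
    "induced_partition",
    "is_compatible",
    "enumerate_compatible_partitions",
    "count_compatible_partitions",
    "DEFAULT_PARTITION_CAP",
]

#: Refuse to enumerate more candidate partitions than this unless overridden.
#: Enumeration beyond roughly 15 unknown tips is memory-prohibitive.
DEFAULT_PARTITION_CAP = 20_000_000


class SpeciesPartition:
    """An assignment of every tip label to exactly one species.

    Blocks are canonicalized: labels sorted within each block, blocks sorted
    by their smallest label.  Equality and hashing follow the canonical form,
    so partitions are usable as dict keys.

    Parameters
    ----------
    blocks : iterable of iterables of str
        Non-empty, pairwise-disjoint label sets.
    names : sequence of str, optional
        Species name per block, aligned with the *canonical* block order.
    """

    __slots__ = ("_blocks", "_names", "_label_to_block", "_hash")

    def __init__(self, blocks, names: Optional[Iterable[str]] = None):
        canon = []
        for block in blocks:
            block = tuple(sorted(block))
            if not block:
                raise InputError("empty species block")
            canon.append(block)
        canon.sort(key=lambda b: b[0])
        self._blocks = tuple(canon)
        seen = {}
        for i, block in enumerate(self._blocks):
            for label in block:
                if label in seen:
                    raise InputError(f"label {label!r} appears in two blocks")
                seen[label] = i
        self._label_to_block = seen
        self._names = tuple(names) if names is not None else None
        if self._names is not None and len(self._names) != len(self._blocks):
            raise InputError("one species name per block required")
        self._hash = hash(self._blocks)

    @classmethod
    def from_assignments(cls, assignments: Mapping[str, str]) -> "SpeciesPartition":
        """Build from a tip-label -> species-name map covering all tips."""
        by_name: dict = {}
        for label, name in assignments.items():
            by_name.setdefault(name, []).append(label)
        blocks = [tuple(sorted(v)) for v in by_name.values()]
        order = sorted(range(len(blocks)), key=lambda i: blocks[i][0])
        names = list(by_name.keys())
        return cls([blocks[i] for i in order], names=[names[i] for i in order])

    @property
    def blocks(self) -> tuple:
        return self._blocks

    @property
    def names(self) -> Optional[tuple]:
        return self._names

    @property
    def n_species(self) -> int:
        return len(self._blocks)

    @property
    def labels(self) -> frozenset:
        return frozenset(self._label_to_block)

    def block_of(self, label: str) -> int:
        """Canonical index of the block containing ``label``."""
        return self._label_to_block[label]

    def same_species(self, labels: Iterable[str]) -> bool:
        idx = {self._label_to_block[l] for l in labels}
        return len(idx) == 1

    def restricted_to(self, labels: Iterable[str]) -> "SpeciesPartition":
        keep = set(labels)
        blocks = [
            [l for l in block if l in keep]
            for block in self._blocks
        ]
        return SpeciesPartition([b for b in blocks if b])

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesPartition) and self._blocks == other._blocks

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        inner = "; ".join(",".join(b) for b in self._blocks)
        return f"SpeciesPartition({inner})"

    def sort_key(self) -> tuple:
        """Deterministic total order used for tie-breaking in rankings."""
        return (len(self._blocks), self._blocks)


class ConstraintSet:
    """Partial map from tip labels to a-priori species names.

    Tips without an entry are of unknown species identity.  The induced
    relation on the constrained subset is an equivalence: two constrained
    tips are conspecific iff they carry the same species name.
    """

    __slots__ = ("_assignments",)

    def __init__(self, assignments: Optional[Mapping[str, str]] = None):
        assignments = dict(assignments or {})
        for label, name in assignments.items():
            if not name:
                raise ConstraintError(f"empty species name for tip {label!r}")
        self._assignments = assignments

    @property
    def assignments(self) -> dict:
        return dict(self._assignments)

    @property
    def constrained_labels(self) -> frozenset:
        return frozenset(self._assignments)

    def __len__(self) -> int:
        return len(self._assignments)

    def __bool__(self) -> bool:
        return bool(self._assignments)

    def species_blocks(self) -> dict:
        """Map species name -> sorted tuple of constrained tips."""
        out: dict = {}
        for label, name in self._assignments.items():
            out.setdefault(name, []).append(label)
        return {name: tuple(sorted(v)) for name, v in out.items()}

    def constrained_partition(self) -> SpeciesPartition:
        """The partition of the constrained subset implied by the names."""
        if not self._assignments:
            raise ConstraintError("no constrained tips")
        return SpeciesPartition.from_assignments(self._assignments)

    def has_conspecific_pair(self) -> bool:
        return any(len(b) >= 2 for b in self.species_blocks().values())

    def has_heterospecific_pair(self) -> bool:
        return len(self.species_blocks()) >= 2

    def validate_against(self, tree: LineageTree) -> None:
        unknown = self.constrained_labels - tree.leaf_label_set
        if unknown:
            raise ConstraintError(
                f"constrained tips not in tree: {sorted(unknown)}"
            )

    def __repr__(self) -> str:
        return f"ConstraintSet({self._assignments!r})"


class EventConfiguration:
    """Per-branch indicator of speciation-completion events.

    The configuration is bound to a specific :class:`LineageTree`; entry *i*
    refers to branch *i* of ``tree.branches``.  ``events[i]`` is 1 when at
    least one completion event occurred on that branch.  Integer event counts
    may be retained for diagnostics (the likelihood depends only on 0 vs >=1).
    """

    __slots__ = ("tree", "events", "counts")

    def __init__(self, tree: LineageTree, events, counts=None):
        events = np.asarray(events, dtype=np.int8)
        if events.shape != (tree.n_branches,):
            raise ConfigurationDomainError(
                f"configuration covers {events.shape[0]} branches but the "
                f"tree has {tree.n_branches}"
            )
        if counts is not None:
            counts = np.asarray(counts, dtype=int)
            if counts.shape != events.shape:
                raise ConfigurationDomainError("counts/events length mismatch")
            if not np.array_equal(counts > 0, events > 0):
                raise ConfigurationDomainError(
                    "event indicators disagree with event counts"
                )
        self.tree = tree
        self.events = events
        self.counts = counts

    @property
    def n_event_branches(self) -> int:
        return int(self.events.sum())

    def __repr__(self) -> str:
        return f"EventConfiguration(events={self.events.tolist()})"


def induced_partition(
    tree: LineageTree, config: EventConfiguration
) -> SpeciesPartition:
    """Species partition induced by an event configuration.

    Two tips are conspecific iff every branch on the path between them
    (through the root if needed) carries no completion event; equivalently,
    the blocks are the leaf sets of the connected components left after
    deleting every event branch.
    """
    if config.tree is not tree:
        raise ConfigurationDomainError(
            "configuration was built for a different tree"
        )
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for node in tree.postorder_nodes():
        parent[node] = node
    for i, node in enumerate(tree.branches):
        if config.events[i] == 0:
            ra, rb = find(node), find(node.parent_node)
            if ra is not rb:
                parent[ra] = rb
    blocks: dict = {}
    for node in tree.postorder_nodes():
        if node.is_leaf():
            blocks.setdefault(find(node), []).append(node.taxon.label)
    return SpeciesPartition(blocks.values())


def is_compatible(partition: SpeciesPartition, constraints: ConstraintSet) -> bool:
    """Whether a partition honours every constraint.

    Conspecific constrained pairs must share a block, heterospecific pairs
    must not; equivalently, each named species' tips occupy exactly one block
    and no block holds tips of two different species names.
    """
    missing = constraints.constrained_labels - partition.labels
    if missing:
        raise InputError(
            f"constrained tips missing from partition: {sorted(missing)}"
        )
    block_name: dict = {}
    for label, name in constraints.assignments.items():
        idx = partition.block_of(label)
        if block_name.setdefault(idx, name) != name:
            return False  # block merges two named species
    name_block: dict = {}
    for idx, name in block_name.items():
        if name_block.setdefault(name, idx) != idx:
            return False  # one named species split over two blocks
    return True


def count_compatible_partitions(n_unknown: int, n_species: int) -> int:
    """Number of full-leaf-set partitions compatible with the constraints.

    Constrained species act as ``n_species`` pre-merged, unmergeable atoms;
    each of the ``n_unknown`` unknown tips joins an existing species or
    groups with other unknowns into new species.  With no constraints this
    is the Bell number of ``n_unknown``.
    """
    # c[j] = number of completions given j new (unknown-only) blocks so far
    if n_unknown < 0 or n_species < 0:
        raise InputError("negative counts")
    counts = {0: 1}
    for _ in range(n_unknown):
        nxt: dict = {}
        for j, ways in counts.items():
            nxt[j] = nxt.get(j, 0) + ways * (n_species + j)
            nxt[j + 1] = nxt.get(j + 1, 0) + ways
        counts = nxt
    return sum(counts.values())


def enumerate_compatible_partitions(
    leaves: Iterable[str],
    constraints: Optional[ConstraintSet] = None,
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
) -> Iterator[SpeciesPartition]:
    """Yield every partition of ``leaves`` compatible with ``constraints``.

    Enumeration follows restricted-growth strings over atoms (constrained
    species first, in order of their smallest tip label, then unknown tips in
    sorted order), so the order is deterministic.  With no constraints all
    Bell(n) partitions are produced.

    Raises
    ------
    EnumerationCapError
        Before any yield, when the compatible-partition count exceeds ``cap``
        (pass ``cap=None`` to disable the guard).
    """
    leaves = sorted(set(leaves))
    constraints = constraints or ConstraintSet()
    extra = constraints.constrained_labels - set(leaves)
    if extra:
        raise ConstraintError(f"constrained tips not among leaves: {sorted(extra)}")
    species_atoms = sorted(constraints.species_blocks().values(), key=lambda b: b[0])
    unknown = [l for l in leaves if l not in constraints.constrained_labels]
    total = count_compatible_partitions(len(unknown), len(species_atoms))
    if cap is not None and total > cap:
        raise EnumerationCapError(total, cap)

    n_species = len(species_atoms)
    atoms = [list(b) for b in species_atoms] + [[l] for l in unknown]

    def recurse(i: int, blocks: list):
        if i == len(atoms):
            yield SpeciesPartition(
                [list(itertools.chain.from_iterable(b)) for b in blocks]
            )
            return
        # join an existing block (never merging two species atoms: blocks
        # indexed < n_species each contain one species atom already, and
        # species atoms are placed first, so only unknown atoms reach here
        # with a choice)
        for j in range(len(blocks)):
            blocks[j].append(atoms[i])
            yield from recurse(i + 1, blocks)
            blocks[j].pop()
        blocks.append([atoms[i]])
        yield from recurse(i + 1, blocks)
        blocks.pop()

    def recurse_top():
        if not atoms:
            return
        if n_species:
            # each named species opens its own block, in order
            blocks = [[atom] for atom in atoms[:n_species]]
            yield from recurse(n_species, blocks)
        else:
            yield from recurse(0, [])

    return recurse_top()
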