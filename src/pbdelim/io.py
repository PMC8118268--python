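"""File formats: Newick trees, constraint tables, results and metadata.

Constraints are tab-separated with header ``lineage<TAB>species<TAB>status``:
status 1 marks a constrained tip (its species name is used), status 0 an
unknown tip (species column ignored).  A two-column ``lineage<TAB>species``
variant is accepted, with ``?`` in the species column marking unknown tips.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional

import dendropy

from .exceptions import ConstraintError, InputError
from .partition import ConstraintSet
from .simulate import SimulatedDataset
from .tree import LineageTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "read_trees",
    "write_tree",
    "read_constraints",
    "write_constraints",
    "write_dataset",
    "load_results_schema",
    "validate_results",
]


def read_tree(path) -> LineageTree:
    """Read a single rooted Newick tree with branch durations."""
    trees = read_trees(path)
    if len(trees) != 1:
        raise InputError(f"{path} holds {len(trees)} trees; expected exactly 1")
    return trees[0]


def read_trees(path) -> List[LineageTree]:
    """Read one or more Newick trees (e.g. a posterior sample) from a file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"tree file not found: {path}")
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise InputError(f"could not parse Newick file {path}: {exc}") from exc
    if not tree_list:
        raise InputError(f"no trees found in {path}")
    return [LineageTree(t) for t in tree_list]


def write_tree(tree: LineageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_constraints(path, tree: Optional[LineageTree] = None) -> ConstraintSet:
    """Read a constraints TSV; optionally validate the labels against a tree."""
    path = Path(path)
    if not path.exists():
        raise ConstraintError(f"constraints file not found: {path}")
    assignments = {}
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "lineage":
                continue  # header
            if len(fields) == 2:
                label, species = (f.strip() for f in fields)
                status = "0" if species == "?" else "1"
            elif len(fields) >= 3:
                label, species, status = (f.strip() for f in fields[:3])
            else:
                raise ConstraintError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not label:
                raise ConstraintError(f"{path}:{lineno}: empty lineage label")
            if label in seen:
                raise ConstraintError(f"{path}:{lineno}: duplicate tip {label!r}")
            seen.add(label)
            if status == "1":
                if not species or species == "?":
                    raise ConstraintError(
                        f"{path}:{lineno}: constrained tip {label!r} needs a "
                        "species name"
                    )
                assignments[label] = species
            elif status == "0":
                continue
            else:
                raise ConstraintError(
                    f"{path}:{lineno}: status must be 0 or 1, got {status!r}"
                )
    constraints = ConstraintSet(assignments)
    if tree is not None:
        constraints.validate_against(tree)
        missing = tree.leaf_label_set - seen
        if missing:
            logger.info(
                "%d tree tips absent from the constraints file are treated "
                "as unknown", len(missing),
            )
    if constraints and not constraints.has_conspecific_pair():
        logger.warning(
            "constraints contain no conspecific pair; the completion-rate "
            "estimate will sit at the infinite boundary"
        )
    if constraints and not constraints.has_heterospecific_pair():
        logger.warning(
            "constraints contain no heterospecific pair; the completion-rate "
            "estimate will sit at the zero boundary"
        )
    return constraints


def write_constraints(constraints: ConstraintSet, path, tree=None) -> None:
    """Write the three-column constraints TSV (unknown tips included when a
    tree is supplied)."""
    with open(path, "w") as fh:
        fh.write("lineage\tspecies\tstatus\n")
        for label in sorted(constraints.constrained_labels):
            fh.write(f"{label}\t{constraints.assignments[label]}\t1\n")
        if tree is not None:
            for label in sorted(tree.leaf_label_set - constraints.constrained_labels):
                fh.write(f"{label}\t?\t0\n")


def write_dataset(dataset: SimulatedDataset, prefix) -> dict:
    """Write a simulated dataset as Newick + truth TSV + JSON metadata.

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": prefix.with_suffix(".nwk"),
        "truth": prefix.with_suffix(".truth.tsv"),
        "meta": prefix.with_suffix(".meta.json"),
    }
    write_tree(dataset.tree, paths["tree"])
    dataset.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["meta"], "w") as fh:
        json.dump(dataset.metadata(), fh, indent=2)
        fh.write("\n")
    return paths


def load_results_schema() -> dict:
    """The shipped JSON schema describing delimitation result documents."""
    schema_path = Path(__file__).parent / "schemas" / "results.schema.json"
    with open(schema_path) as fh:
        return json.load(fh)


def validate_results(document: dict) -> None:
    """Structural check of a results document against the shipped schema.

    Covers required keys and primitive types (a deliberately small validator;
    the schema file itself is the normative description).
    """
    schema = load_results_schema()
    _validate_node(document, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _validate_node(value, schema, where):
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if value is None:
            if "null" not in types:
                raise InputError(f"{where}: unexpected null")
        else:
            ok = any(isinstance(value, _TYPES[t]) for t in types if t != "null")
            # bools are ints in Python; keep number/integer honest
            if isinstance(value, bool) and "boolean" not in types:
                ok = False
            if not ok:
                raise InputError(
                    f"{where}: expected {types}, got {type(value).__name__}"
                )
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise InputError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{where}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate_node(item, schema["items"], f"{where}[{i}]")
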