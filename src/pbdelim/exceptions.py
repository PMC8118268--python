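"""Exception hierarchy.

All user-input problems derive from :class:`InputError` so that callers (and
the command-line layer, which maps exception classes onto exit codes) can
distinguish bad input from internal failures.
"""


class PbdelimError(Exception):
    """Base class for all package errors."""


class InputError(PbdelimError, ValueError):
    """Invalid user input (malformed file, unknown label, bad parameter)."""


class TreeStructureError(InputError):
    """A tree violates the lineage-tree invariants (missing or non-positive
    branch durations, duplicate or empty leaf labels, fewer than two leaves)."""


class ConfigurationDomainError(InputError):
    """An event configuration does not cover exactly the tree's branch set."""


class ConstraintError(InputError):
    """A constraint table is inconsistent or references unknown tips."""


class EnumerationCapError(PbdelimError):
    """Refusal to enumerate a partition space larger than the configured cap."""

    def __init__(self, n_partitions, cap):
        self.n_partitions = int(n_partitions)
        self.cap = int(cap)
        super().__init__(
            f"{self.n_partitions} candidate partitions exceed the enumeration "
            f"cap of {self.cap}; raise the cap explicitly to proceed"
        )
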