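"""Exception hierarchy shared across pedcraft modules."""


class PedigreeError(Exception):
    """Base class for all pedcraft errors."""


class StructuralError(PedigreeError):
    """The parent-child graph violates a structural requirement (e.g. a cycle)."""


class CycleError(StructuralError):
    """A directed cycle was found; renumbering and kinship are undefined."""

    def __init__(self, member: int):
        self.member = member
        super().__init__(f"pedigree contains a cycle through person {member}")


class DataError(PedigreeError):
    """A person record or link set is internally inconsistent (e.g. >2 parents)."""


class UnknownPidError(PedigreeError, KeyError):
    """A pid was referenced that is not present in the dataset."""

    def __init__(self, pid):
        self.pid = pid
        super().__init__(f"unknown pid {pid!r}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return f"unknown pid {self.pid!r}"


class ContractError(PedigreeError):
    """A precondition of an operation was violated by the caller."""


class PedigreeParseError(PedigreeError, ValueError):
    """Malformed text input (LINKAGE rows, pair files, tables)."""


class ArgumentError(PedigreeError, ValueError):
    """An argument value is out of its permitted range."""


class ConfigurationError(PedigreeError):
    """Rules or bin configuration is incomplete or overlapping."""
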