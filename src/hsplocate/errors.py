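"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`HspLocateError`, so callers can catch one base class. Input problems
additionally derive from :class:`ValueError` (or :class:`KeyError` for
lookups) to behave like ordinary Python errors.
"""

from __future__ import annotations


class HspLocateError(Exception):
    """Base class for all errors raised by hsplocate."""


class InvalidInputError(HspLocateError, ValueError):
    """An argument violates a documented precondition (non-finite, negative, wrong shape...)."""


class SchemaError(InvalidInputError):
    """A tabular input file is missing a required column."""


class DegenerateWeightsError(InvalidInputError):
    """The absorbance weight vector carries no information (all zero)."""


class DataValidationError(HspLocateError):
    """A database or measurement table violates its invariants.

    Carries the full list of :class:`~hsplocate.database.Issue` objects so a
    caller can report every problem at once.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"{len(self.issues)} validation issue(s): {lines}")


class SolventNotFoundError(HspLocateError, KeyError):
    """A solvent key resolved to no database record."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(f"no solvent matching {key!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class AmbiguousSolventError(HspLocateError, LookupError):
    """A solvent key matched more than one record."""

    def __init__(self, key: str, candidates):
        self.key = key
        self.candidates = list(candidates)
        names = ", ".join(c.cas for c in self.candidates)
        super().__init__(f"solvent key {key!r} is ambiguous between CAS [{names}]")


class GridTooLargeError(HspLocateError):
    """A brute-force grid would exceed the configured cell cap."""
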