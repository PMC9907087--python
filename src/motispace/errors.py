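"""Exception hierarchy shared across the package."""


class MotispaceError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MotispaceError, ValueError):
    """An item label is outside the domain under analysis, or a subset is invalid."""


class TransitivityError(MotispaceError, ValueError):
    """A pair set declared transitive is not; carries a violating triple."""

    def __init__(self, triple):
        self.triple = tuple(triple)
        x, y, z = self.triple
        super().__init__(
            f"relation is not transitive: {x} ⊑ {y} and {y} ⊑ {z} "
            f"but not {x} ⊑ {z}"
        )


class CapacityError(MotispaceError, RuntimeError):
    """An enumeration would exceed its configured cap."""

    def __init__(self, message, bound):
        self.bound = bound
        super().__init__(f"{message} (cap: {bound})")


class EmptyDatasetError(MotispaceError, ValueError):
    """No rows survived filtering, or an input table is empty."""


class FixtureLookupError(MotispaceError, KeyError):
    """Unknown fixture name; the message lists the valid ones."""


class ParseError(MotispaceError, ValueError):
    """A data file is malformed; carries the offending line number."""

    def __init__(self, message, line_no=None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
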