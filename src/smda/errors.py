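"""Exception hierarchy shared across the package."""


class SmdaError(Exception):
    """Base class for all errors raised by this package."""


class UnknownEntityError(SmdaError, KeyError):
    """A referenced compartment, metabolite, pool, reaction or pathway is not registered."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ValidationError(SmdaError, ValueError):
    """Input violates a structural or semantic constraint."""


class SchemaError(ValidationError):
    """A serialized document does not conform to the native format."""


class CapacityError(SmdaError, RuntimeError):
    """A guarded computation exceeded its configured size limit."""


class NoReferenceRangeError(SmdaError, LookupError):
    """No reference range is available to convert a concentration into a label."""
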