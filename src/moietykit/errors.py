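"""Exception types shared across moietykit."""


class MoietykitError(Exception):
    """Base class for all moietykit errors."""


class ModelDefinitionError(MoietykitError):
    """A moiety model violates a structural invariant (bad state content,
    duplicate states, circular relationships, ...)."""


class SchemaError(MoietykitError):
    """A JSON document does not conform to the documented schema.

    The message names the offending field.
    """


class GridMismatchError(MoietykitError):
    """Two isotopologue profiles do not share the same content grid."""
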