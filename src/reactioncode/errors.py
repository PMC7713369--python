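"""Exception hierarchy for the reactioncode package."""


class ReactionCodeError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ReactionCodeError):
    """Malformed input text (SMILES, RXN, RDF or a ReactionCode string).

    Carries the character position (for line notations / codes) or line
    number (for CTfile formats) when known.
    """

    def __init__(self, message, *, pos=None, line=None):
        ctx = []
        if line is not None:
            ctx.append(f"line {line}")
        if pos is not None:
            ctx.append(f"position {pos}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.pos = pos
        self.line = line


class MappingError(ReactionCodeError):
    """Missing, duplicated or corrupted atom-atom mapping."""


class EmptyReactionCenterError(ReactionCodeError):
    """No bond differs between reactant and product sides.

    Changes in charge, stereochemistry, isotope or radical status alone do
    not constitute a reaction center.
    """


class EncodingError(ReactionCodeError):
    """The CGR cannot be serialized (index overflow, unsupported element...)."""


class DecodingError(ReactionCodeError):
    """A structurally valid code cannot be turned back into molecules."""


class KekulizationFailure(DecodingError):
    """A decoded aromatic system admitted no Kekulé assignment."""


class FixtureError(ReactionCodeError):
    """The synthetic-reaction generator was given an infeasible request."""
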