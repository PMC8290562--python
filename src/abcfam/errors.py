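"""Exception hierarchy.

All package-raised errors derive from :class:`AbcfamError` so the CLI can
map validation problems onto a single exit code.
"""


class AbcfamError(Exception):
    """Base class for all errors raised by abcfam."""


class ParseError(AbcfamError, ValueError):
    """An external file did not conform to its dialect."""


class ValidationError(AbcfamError, ValueError):
    """Inputs violated a documented precondition."""
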