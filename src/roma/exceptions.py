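"""Exception hierarchy."""


class RomaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RomaError):
    """Malformed input file (expression table, GMT, annotation)."""


class DegenerateModuleError(RomaError):
    """Module submatrix has zero weighted variance after centering."""
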