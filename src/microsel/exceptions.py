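"""Exception hierarchy.

``InputError`` covers anything a user can fix (bad files, bad parameters);
``FitError`` covers numerical failures inside model fitting. The CLI maps
``MicroselError`` subclasses to exit code 1 and anything else to exit code 2.
"""


class MicroselError(Exception):
    """Base class for all errors raised by this package."""


class InputError(MicroselError):
    """Invalid user input: malformed file, bad parameter, contract violation."""


class FitError(MicroselError):
    """Model fitting failed (degenerate data, singular system, eta too large)."""
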