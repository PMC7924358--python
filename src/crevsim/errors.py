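"""Exception hierarchy for crevsim."""


class CrevSimError(Exception):
    """Base class for all crevsim errors."""


class InputError(CrevSimError, ValueError):
    """Invalid user input: bad geometry, malformed profile, unit mismatch."""


class NumericalError(CrevSimError, RuntimeError):
    """A computation could not be carried out reliably (degenerate fit, etc.)."""
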