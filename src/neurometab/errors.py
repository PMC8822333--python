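"""Exception hierarchy used across the pipeline."""


class NeurometabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeurometabError, ValueError):
    """A configuration value is out of its valid domain."""


class InputError(NeurometabError, ValueError):
    """Inputs are malformed or mutually inconsistent (shape/label mismatch)."""


class DegenerateInputError(NeurometabError, ValueError):
    """Inputs are structurally valid but too degenerate to operate on."""


class NumericDomainError(NeurometabError, ValueError):
    """A value lies outside the numeric domain of a transform (e.g. log of <= 0)."""


class EmptyNetworkError(NeurometabError, ValueError):
    """No association passed the edge criteria; there is no network to analyze."""
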