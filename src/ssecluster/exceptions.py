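"""Exception hierarchy shared across the package."""


class SSEClusterError(Exception):
    """Base class for all package errors."""


class InputError(SSEClusterError, ValueError):
    """Invalid user-supplied data (negative entries, shape mismatches, ...)."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(SSEClusterError, ValueError):
    """Invalid configuration value (e.g. k >= number of cells)."""


class GraphError(SSEClusterError, RuntimeError):
    """Graph is degenerate for the requested operation (e.g. no edges)."""


class SizeError(SSEClusterError, ValueError):
    """Problem size outside the supported range of an exhaustive routine."""
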