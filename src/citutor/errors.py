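"""Exception hierarchy shared across the package."""


class CITutorError(Exception):
    """Base class for all package-specific errors."""


class ContractError(CITutorError, ValueError):
    """An operation was called with arguments violating its contract."""


class NetworkValidationError(CITutorError, ValueError):
    """A network description is malformed (bad node, arc, or cycle)."""


class DegenerateEvidenceError(CITutorError, ValueError):
    """An evidence vector is all zero, so the posterior is undefined."""


class NodeLookupError(CITutorError, KeyError):
    """A referenced node does not exist or has the wrong layer."""


class StateParseError(CITutorError, ValueError):
    """Serialized network state could not be parsed."""


class PoolValidationError(CITutorError, ValueError):
    """An asset manifest failed validation."""


class EmptyPoolError(CITutorError, ValueError):
    """No eligible candidate task exists for the requested task type."""


class DegenerateDataError(CITutorError, ValueError):
    """Statistics are undefined for the given data (e.g. all values tied)."""


class LogParseError(CITutorError, ValueError):
    """An event-log line could not be parsed."""


class ConfigValidationError(CITutorError, ValueError):
    """A run configuration failed validation."""
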