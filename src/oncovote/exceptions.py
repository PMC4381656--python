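"""Exception hierarchy shared across the pipeline stages."""


class OncovoteError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OncovoteError):
    """A line of an input file could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class EmptyNetworkError(OncovoteError):
    """The parsed edge list contained no edges."""


class DomainlessProteinError(OncovoteError):
    """An operation required domain annotations for a protein that has none."""


class EmptySelectionError(OncovoteError):
    """An edge-class selector matched no edges."""


class ProvenanceError(OncovoteError):
    """Two artifacts that must share provenance (edge subset, network) do not."""


class DegenerateTableError(OncovoteError):
    """A frequency table with m + n = 0 cannot weight domain scores."""


class StratificationError(OncovoteError):
    """Cross-validation folds cannot be stratified (a class is too small)."""


class SizeError(OncovoteError):
    """Balanced sampling is impossible (fewer negatives than positives)."""


class ConfigError(OncovoteError):
    """An invalid run or generator configuration."""
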