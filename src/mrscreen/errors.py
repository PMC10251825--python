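"""Exception hierarchy shared across the package."""


class MRScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRScreenError):
    """Invalid user configuration (missing columns, bad thresholds, bad paths)."""


class EmptyDatasetError(MRScreenError):
    """A dataset or harmonized set with zero usable records where at least one is required."""


class PanelLookupError(MRScreenError, KeyError):
    """A variant id is not present in the LD panel."""


class UndefinedLDError(MRScreenError):
    """LD is undefined (e.g. a zero-variance dosage vector)."""


class HarmonizationError(MRScreenError):
    """Structurally invalid harmonization request (e.g. mismatched variant ids)."""


class InsufficientInstrumentsError(MRScreenError):
    """An estimator was called with fewer instruments than it requires."""


class DegenerateModelError(MRScreenError):
    """Degenerate regression input (e.g. constant exposure effects for MR-Egger)."""


class DomainError(MRScreenError, ValueError):
    """An argument outside a formula's mathematical domain."""
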