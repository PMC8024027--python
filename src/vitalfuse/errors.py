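"""Structured exceptions shared across the package."""


class VitalfuseError(Exception):
    """Base class for all package errors."""


class DimensionError(VitalfuseError):
    """Shapes of labels, mask, state and design matrix disagree."""


class ConfigurationError(VitalfuseError):
    """Invalid hyperparameter, mode string or run configuration."""


class NumericalStateError(VitalfuseError):
    """A sampler reached an invalid numerical state (e.g. non-SPD covariance)."""


class InputError(VitalfuseError):
    """Malformed user input: files, CSV cells, degenerate datasets."""
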