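"""Exception hierarchy for the radbatch pipeline."""


class RadbatchError(Exception):
    """Base class for all radbatch errors."""


class GeometryError(RadbatchError):
    """Invalid spatial layout (overlapping rods, mask touching the edge...)."""


class FormatError(RadbatchError):
    """A volume or mask file could not be parsed."""


class ConfigError(RadbatchError):
    """Invalid configuration value (unknown kernel, bad threshold...)."""


class ExtractionError(RadbatchError):
    """Feature extraction is impossible (empty ROI, degenerate geometry)."""


class PairingError(RadbatchError):
    """Subjects of two protocols cannot be matched one-to-one."""
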