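"""Exception hierarchy.

Detection failures (the scene did not contain what a stage looked for) are kept
distinct from format/configuration problems so a field campaign can triage
failed rows automatically.
"""


class HsirowError(Exception):
    """Base class for all package errors."""


class FormatError(HsirowError):
    """A raster file or header is malformed; the message names the field."""


class ConfigError(HsirowError):
    """Invalid pipeline or scene configuration; the message names the key."""


class DetectionError(HsirowError):
    """A detection stage failed on an otherwise valid image."""


class DegenerateInputError(HsirowError):
    """An input is degenerate for the requested operation (e.g. constant image)."""
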