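"""Exception types raised across the package."""


class ParotidSegError(Exception):
    """Base class for package errors."""


class InvalidSpecError(ParotidSegError, ValueError):
    """A phantom specification violates its invariants."""


class ConfigError(ParotidSegError, ValueError):
    """A model or training configuration is inconsistent."""


class RegistrationError(ParotidSegError, ValueError):
    """Sequences or masks of one case do not share a common grid."""


class FormatError(ParotidSegError, ValueError):
    """An input file or manifest entry is malformed."""


class MissingSequenceError(ParotidSegError, KeyError):
    """A requested MRI sequence is absent from a case."""


class MaskValidationError(ParotidSegError, ValueError):
    """A label volume contains values outside {0, 1} or a bad shape."""
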