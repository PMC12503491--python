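"""Exception types shared across the package."""


class DvcAtlasError(Exception):
    """Base class for all package-specific errors."""


class InputError(DvcAtlasError):
    """A required input file or directory is missing."""


class FormatError(DvcAtlasError):
    """A file exists but its contents violate the expected format."""


class ValidationError(DvcAtlasError):
    """In-memory data violates a structural invariant."""
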