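"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file or array violates the expected format (dims, grids, echoes)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent run configuration (sidecars, plans, specs)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information
    (constant image, empty mask, no co-occurring pairs)."""
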