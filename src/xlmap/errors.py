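"""Exception hierarchy; every fatal pipeline condition maps to one of these."""


class XlmapError(Exception):
    """Base class for all tool-level errors."""


class EmptyInputError(XlmapError):
    """An input file contained no usable records."""


class InputFormatError(XlmapError):
    """An input file is malformed beyond row-level recovery."""


class StructureParseError(XlmapError):
    """A structure file could not be parsed or holds no polymer chains."""


class UnknownLinkerError(XlmapError):
    """A cross-link references a linker absent from the linker table."""


class ConfigError(XlmapError):
    """The run configuration is invalid or references missing paths."""


class SceneError(XlmapError):
    """A synthetic scene cannot be built with the requested parameters."""
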