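"""Exception hierarchy for the nucleus shell-analysis pipeline."""


class NucshellError(Exception):
    """Base class for all pipeline errors."""


class InputError(NucshellError):
    """Unreadable, undecodable, or otherwise invalid input image or file."""


class ParameterError(NucshellError):
    """Invalid configuration parameter (shell count, radii, palette, ...)."""


class NoNucleusError(NucshellError):
    """No nucleus (counterstain or probe) pixel found anywhere in the image."""


class DegenerateNucleusError(NucshellError):
    """Nucleus too small or degenerate for axis estimation."""


class GeometryError(NucshellError):
    """Inconsistent geometry, e.g. a midpoint falling outside the contour."""
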