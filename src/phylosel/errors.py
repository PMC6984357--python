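"""Exception hierarchy.

All user-facing errors derive from :class:`PhyloselError` so the CLI can map
them onto exit code 1 (user/input error) versus 2 (internal error).
"""


class PhyloselError(Exception):
    """Base class for all errors raised by phylosel."""


class FormatError(PhyloselError, ValueError):
    """Malformed input file (alignment, partition file, tree)."""


class ValidationError(PhyloselError, ValueError):
    """Structurally well-formed input that violates a semantic invariant."""


class ConfigError(PhyloselError, ValueError):
    """Invalid combination of options or model settings."""


class DomainError(PhyloselError, ValueError):
    """Numeric parameter outside its admissible domain."""


class OptimizationError(PhyloselError, RuntimeError):
    """Likelihood optimization could not produce a finite result."""
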