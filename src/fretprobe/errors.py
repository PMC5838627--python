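"""Typed exceptions shared across the package."""


class FretProbeError(Exception):
    """Base class for all errors raised by fretprobe."""


class AlphabetError(FretProbeError):
    """A sequence contains characters outside the supported DNA alphabet."""


class RangeError(FretProbeError):
    """An offset or coordinate falls outside the target sequence."""


class DomainError(FretProbeError):
    """A numeric argument is outside its physical domain (e.g. negative concentration)."""


class ParameterCoverageError(FretProbeError):
    """The nearest-neighbor table has no entry for a required stack."""

    def __init__(self, stack: str):
        self.stack = stack
        super().__init__(f"no nearest-neighbor parameters for stack {stack!r}")


class UnsupportedDuplexError(FretProbeError):
    """Duplex outside the supported regime (terminal or multiple mismatches)."""


class NoTransitionError(FretProbeError):
    """The two-state model predicts no helix-coil transition for these parameters."""


class GridMismatchError(FretProbeError):
    """Melting curves to be combined do not share a temperature grid."""


class CoverageError(FretProbeError):
    """A candidate probe footprint does not (strictly) cover the SNP position."""


class PlacementError(FretProbeError):
    """No donor-probe placement satisfies the FRET geometry and Tm constraints."""


class ParseError(FretProbeError):
    """A file could not be parsed; carries position information where available."""


class ValidationError(FretProbeError):
    """An input or configuration failed validation."""
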