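"""Exception hierarchy for the arch-stiffness pipeline.

Every rejected input raises a named subclass of :class:`ArchstiffError`
so that the CLI can report the error class on stderr and exit nonzero.
"""


class ArchstiffError(Exception):
    """Base class for all archstiff errors."""


class ParseError(ArchstiffError):
    """A cell in an input file could not be parsed as a number."""


class MissingMarker(ArchstiffError):
    """A required landmark column is absent from the marker file."""


class ClockMismatch(ArchstiffError):
    """Marker and force-plate records do not share a consistent clock."""


class BadMeta(ArchstiffError):
    """Subject metadata violates its invariants (e.g. non-positive mass)."""


class BadWindow(ArchstiffError):
    """A filter window is even, non-positive, or longer than the series."""


class DegenerateFrame(ArchstiffError):
    """Marker geometry in a frame is degenerate (coincident/vertical landmarks)."""


class TooShort(ArchstiffError):
    """Too few frames for the requested differentiation or fit."""


class NoStanceDetected(ArchstiffError):
    """The vertical GRF never produces a qualifying stance window."""


class NoFootFlat(ArchstiffError):
    """The first-metatarsal marker never drops below the height threshold."""


class NoHeelOff(ArchstiffError):
    """The heel marker never re-rises above the height threshold."""


class BadPhaseTime(ArchstiffError):
    """A percent-of-stance value lies outside [0, 100]."""


class DegenerateFit(ArchstiffError):
    """A linear fit is requested on a constant abscissa or too few points."""


class DegenerateReference(ArchstiffError):
    """R-squared reference curve has zero ordinate variance."""


class TooFewSubjects(ArchstiffError):
    """Cohort statistics require at least two subjects."""


class InfeasibleConfig(ArchstiffError):
    """A synthetic-gait configuration cannot be realized (e.g. arch drop > height)."""


class BadConfig(ArchstiffError):
    """Unknown or invalid configuration key/value."""
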