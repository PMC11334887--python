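"""Exception hierarchy.

Every error raised by the library derives from :class:`PlatequantError`.
The ``exit_code`` class attribute groups failures the way the CLI reports
them: 2 for unreadable/malformed inputs, 3 for schema or layout validation,
4 for computation failures (degenerate fits, empty ROIs, ...).
"""


class PlatequantError(Exception):
    """Base class for all library errors."""

    exit_code = 1


class InputError(PlatequantError):
    """A file or table could not be read or is structurally malformed."""

    exit_code = 2


class SchemaError(PlatequantError):
    """Configuration or table content violates the expected schema."""

    exit_code = 3


class LayoutError(SchemaError):
    """Plate layout is invalid (bad address, duplicate well, unknown role)."""


class UnitError(SchemaError):
    """Incommensurable units in the cost model."""


class InvalidSeriesError(SchemaError):
    """A standard/dilution series violates its monotonicity constraints."""


class ROIError(PlatequantError):
    """A region of interest cannot be evaluated on the image."""

    exit_code = 4


class OutOfBoundsError(ROIError):
    """Circle extends beyond the image bounds."""


class EmptyROIError(ROIError):
    """No pixel center falls inside the circle."""


class FitError(PlatequantError):
    """Calibration fit is degenerate (too few points, no concentration spread)."""

    exit_code = 4


class UndetectableError(PlatequantError):
    """No dilution level is statistically distinguishable from the blank."""

    exit_code = 4


class QCError(PlatequantError):
    """Replicate aggregation / recovery inputs are unusable."""

    exit_code = 4
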