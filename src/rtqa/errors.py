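"""Exception hierarchy for rtqa.

Every error raised by the library derives from :class:`RtqaError`, so callers
(including the CLI) can catch one base class. Subclasses are grouped by the
contract they enforce: file-format errors, geometry errors, configuration
errors, and wiring errors (caller bugs, not data problems).
"""


class RtqaError(Exception):
    """Base class for all rtqa errors."""


class FormatError(RtqaError):
    """A DICOM file does not declare the expected storage class."""

    def __init__(self, expected: str, found: str, path: str = ""):
        self.expected = expected
        self.found = found
        super().__init__(
            f"expected storage class {expected}, found {found}"
            + (f" in {path}" if path else "")
        )


class MalformedContourError(RtqaError):
    """A contour's coordinate list cannot be reshaped to (x, y, z) triplets."""

    def __init__(self, roi_number: int, detail: str):
        self.roi_number = roi_number
        super().__init__(f"ROI {roi_number}: {detail}")


class MalformedDoseError(RtqaError):
    """RT Dose grid is missing offsets, non-monotonic, or inconsistent."""


class UnsupportedOrientationError(RtqaError):
    """Only axial, non-tilted (identity direction cosine) grids are supported."""


class DegeneratePhantomError(RtqaError):
    """Phantom spec produces no slices (slice thickness exceeds extent)."""


class OutOfGridError(RtqaError):
    """A contour plane lies farther than tolerance from every dose-grid plane."""


class DegenerateStructureError(RtqaError):
    """A structure rasterizes to zero occupancy (no volume on the grid)."""


class MappingConflictError(RtqaError):
    """Two raw structure names were assigned the same canonical name."""

    def __init__(self, canonical: str, raws):
        self.canonical = canonical
        self.raws = list(raws)
        super().__init__(
            f"raw names {sorted(self.raws)} both mapped to '{canonical}'"
        )


class ConfigurationError(RtqaError):
    """A configuration document (lexicon, schema, flow map, policy) is invalid."""


class VocabularyError(ConfigurationError):
    """A rule references a field outside the declared feature dictionary."""


class DomainError(RtqaError):
    """An input value is outside the mathematical domain of an operation."""


class WiringError(RtqaError):
    """Caller passed mismatched objects (wrong structure, colliding namespace)."""


class ParseError(RtqaError):
    """A narrative does not match its boilerplate skeleton."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class UnknownFieldError(RtqaError):
    """An override or flow references a field no template schema declares."""


class UnhandledIdentifierError(RtqaError):
    """A record carries an identity attribute the anonymization policy omits."""
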