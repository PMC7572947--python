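"""Exception hierarchy shared across the study pipeline."""


class MultisplitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MultisplitError, ValueError):
    """A numeric parameter is outside its admissible range."""


class EmptyDesignError(MultisplitError, ValueError):
    """The apex-to-base extent is too short to hold a single chunk."""


class DegenerateZoneError(MultisplitError, ValueError):
    """A lung zone contains no chunk, so a mid-zone chunk cannot be chosen."""

    def __init__(self, zone: str, subject_id=None):
        self.zone = zone
        self.subject_id = subject_id
        where = f" (subject {subject_id})" if subject_id is not None else ""
        super().__init__(f"zone '{zone}' contains no chunk{where}")


class InfeasibleQuotaError(MultisplitError, ValueError):
    """A per-reader quota exceeds the available pool of chunks."""


class UnknownReaderError(MultisplitError, KeyError):
    """An assignment references a reader without a profile."""


class InsufficientDataError(MultisplitError, ValueError):
    """No pairable unit (>= 2 ratings) exists, so agreement is undefined."""


class InvalidCategoryError(MultisplitError, ValueError):
    """A rating category is unknown to the reliability data at hand."""


class DegenerateTableError(MultisplitError, ValueError):
    """A contingency table collapses to fewer than 2 rows or columns."""


class ReferentialIntegrityError(MultisplitError, ValueError):
    """Rows of one table cannot be joined to their parent table."""

    def __init__(self, message: str, offenders=None):
        self.offenders = offenders
        super().__init__(message)


class SchemaError(MultisplitError, ValueError):
    """An input file violates its documented column schema."""

    def __init__(self, message: str, file=None, row=None, column=None):
        self.file = file
        self.row = row
        self.column = column
        loc = "".join(
            f" [{k}={v}]"
            for k, v in (("file", file), ("row", row), ("column", column))
            if v is not None
        )
        super().__init__(message + loc)
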