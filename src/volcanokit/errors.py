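"""Exception hierarchy.

Every error raised by the library derives from :class:`VolcanoKitError`,
so callers (notably the CLI) can distinguish pipeline failures from bugs.
"""


class VolcanoKitError(Exception):
    """Base class for all volcanokit errors."""


class UndelimitedInputError(VolcanoKitError):
    """No candidate delimiter splits the input into at least two fields."""


class UnsupportedFormatError(VolcanoKitError):
    """File extension or export format is not one the package handles."""


class SheetNotFoundError(VolcanoKitError):
    """A named workbook sheet does not exist; message lists available sheets."""


class FileTooLargeError(VolcanoKitError):
    """Input exceeds the configured size guard."""


class RemoteFetchError(VolcanoKitError):
    """Remote download failed (non-2xx status, timeout, or transport error)."""


class UnsupportedSchemeError(VolcanoKitError):
    """Remote URL scheme is not http/https."""


class ColumnNotFoundError(VolcanoKitError):
    """Requested column is absent (or x and y name the same column)."""


class NoNumericDataError(VolcanoKitError):
    """After coercion no row has finite coordinates."""


class ForeignRecordError(VolcanoKitError):
    """A record offered for annotation does not belong to the dataset."""


class ShareUrlError(VolcanoKitError):
    """A string is not a share URL, or a section payload is malformed."""


class NoDataSourceError(VolcanoKitError):
    """A shared state carries neither a data URL nor a resolvable source."""


class NothingToPlotError(VolcanoKitError):
    """Render was asked to draw an empty dataset."""
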