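"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`SitescanError` so the CLI can
map any of them to a nonzero exit with a readable message.
"""


class SitescanError(Exception):
    """Base class for all package errors."""


class FormatError(SitescanError):
    """A file does not conform to the expected format grammar."""


class ValidationError(SitescanError):
    """Inputs violate a documented precondition."""


class MissingDataError(SitescanError):
    """A bundled reference data file is absent (see scripts/fetch_data.py)."""
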