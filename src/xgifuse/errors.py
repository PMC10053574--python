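"""Exception hierarchy shared across the pipeline.

Distinct classes map to distinct CLI exit codes: validation problems
(bad parameters, malformed inputs) are the user's to fix, I/O problems
point at the filesystem, anything else is an internal defect.
"""


class XGIFuseError(Exception):
    """Base class for all package errors."""


class ValidationError(XGIFuseError, ValueError):
    """An input or parameter violates a documented contract."""


class ImageIOError(XGIFuseError, IOError):
    """A file could not be read or written."""
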