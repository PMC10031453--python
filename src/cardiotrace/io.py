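"""File-format surface (alias of :mod:`cardiotrace.recio`).

The implementation lives in ``recio`` so the module file does not shadow the
standard-library ``io`` inside the package; import either name.
"""

from .recio import (  # noqa: F401
    FORMAT_VERSION,
    export_csv,
    read_csv,
    read_native,
    write_native,
)

__all__ = ["FORMAT_VERSION", "write_native", "read_native", "export_csv",
           "read_csv"]
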