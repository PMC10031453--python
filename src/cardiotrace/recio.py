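"""Record file formats: native JSON-lines `.drec` and CSV interchange.

The native format is a versioned JSON-lines dialect: line 1 is a header
object carrying the device description (the DPI needed for mm conversion
lives in the file, not in the reader's head), subsequent lines are one event
each. Files are UTF-8 with LF newlines on every platform, and the
write-then-read round trip is exact.

CSV export is the interchange path for downstream spreadsheet/statistics
work: one row per event, optionally with the accumulated positions and mm
conversions appended.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .errors import FormatError
from .events import DeviceSpec, EventStream
from .reconstruct import accumulate

__all__ = ["FORMAT_VERSION", "write_native", "read_native", "export_csv",
           "read_csv"]

FORMAT_VERSION = 1

_CSV_BASE_HEADER = ["t_ms", "dx_counts", "dy_counts"]
_CSV_POS_HEADER = _CSV_BASE_HEADER + ["x_counts", "y_counts", "x_mm", "y_mm"]


def write_native(
    stream: EventStream,
    path,
    params_used: dict | None = None,
    created_utc: str | None = None,
) -> None:
    """Write a stream to the native JSON-lines format.

    ``created_utc`` defaults to the current UTC time; pass a fixed ISO string
    for byte-reproducible files. ``params_used`` records optional simulation
    provenance in the header.
    """
    header = {
        "format_version": FORMAT_VERSION,
        "dpi": int(stream.device.dpi),
        "pinned_axis": stream.device.pinned_axis,
        "sample_interval_ms": stream.device.sample_interval_ms,
        "created_utc": created_utc
        or datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    if params_used is not None:
        header["params_used"] = params_used
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps(header, separators=(",", ":")) + "\n")
        for t, dx, dy in zip(stream.t_ms, stream.dx, stream.dy):
            fh.write(
                json.dumps(
                    {"t_ms": int(t), "dx": int(dx), "dy": int(dy)},
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_native(path) -> EventStream:
    """Read a native file back into an :class:`EventStream` (exact inverse).

    Raises :class:`FormatError` with the 1-based line number on a version
    mismatch, malformed line, or non-integer delta. The parsed header is
    attached as ``stream.meta``.
    """
    path = Path(path)
    t_ms, dx, dy = [], [], []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise FormatError("empty file, expected a header line", line=1)
        try:
            header = json.loads(first)
        except json.JSONDecodeError as e:
            raise FormatError(f"malformed header: {e.msg}", line=1) from e
        if not isinstance(header, dict) or "format_version" not in header:
            raise FormatError("header must be an object with format_version", line=1)
        if header["format_version"] != FORMAT_VERSION:
            raise FormatError(
                f"unsupported format_version {header['format_version']!r} "
                f"(expected {FORMAT_VERSION})",
                line=1,
            )
        for missing in ("dpi", "pinned_axis", "sample_interval_ms"):
            if missing not in header:
                raise FormatError(f"header missing required field {missing!r}", line=1)

        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as e:
                raise FormatError(f"malformed event: {e.msg}", line=lineno) from e
            try:
                t, x, y = rec["t_ms"], rec["dx"], rec["dy"]
            except (TypeError, KeyError) as e:
                raise FormatError(
                    "event must be an object with t_ms, dx, dy", line=lineno
                ) from e
            for name, v in (("t_ms", t), ("dx", x), ("dy", y)):
                if isinstance(v, bool) or not isinstance(v, int):
                    raise FormatError(
                        f"{name} must be an integer, got {v!r}", line=lineno
                    )
            t_ms.append(t)
            dx.append(x)
            dy.append(y)

    device = DeviceSpec(
        dpi=int(header["dpi"]),
        pinned_axis=header["pinned_axis"],
        sample_interval_ms=header["sample_interval_ms"],
    )
    stream = EventStream(
        device=device,
        t_ms=np.asarray(t_ms, dtype=np.int64),
        dx=np.asarray(dx, dtype=np.int64),
        dy=np.asarray(dy, dtype=np.int64),
        meta=header,
    )
    return stream


def export_csv(stream: EventStream, path, include_positions: bool = False) -> None:
    """Export a stream to CSV, one row per event.

    Base columns are ``t_ms,dx_counts,dy_counts``; with ``include_positions``
    the accumulated positions and their mm conversions (6 decimal places) are
    appended. Decimal points, no thousands separators, LF newlines.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if include_positions:
            writer.writerow(_CSV_POS_HEADER)
            pos = accumulate(stream)
            x_mm = pos.x_mm
            y_mm = pos.y_mm
            for i in range(len(stream)):
                writer.writerow(
                    [
                        int(stream.t_ms[i]),
                        int(stream.dx[i]),
                        int(stream.dy[i]),
                        int(pos.x_counts[i]),
                        int(pos.y_counts[i]),
                        f"{x_mm[i]:.6f}",
                        f"{y_mm[i]:.6f}",
                    ]
                )
        else:
            writer.writerow(_CSV_BASE_HEADER)
            for i in range(len(stream)):
                writer.writerow(
                    [int(stream.t_ms[i]), int(stream.dx[i]), int(stream.dy[i])]
                )


def read_csv(path, device: DeviceSpec) -> EventStream:
    """Import the delta columns of an exported CSV back into a stream.

    Only ``t_ms,dx_counts,dy_counts`` are read; position columns, if present,
    are derived data and ignored. The device must be supplied since CSV
    carries no header metadata.
    """
    t_ms, dx, dy = [], [], []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty CSV file", line=1) from None
        if header[:3] != _CSV_BASE_HEADER:
            raise FormatError(
                f"unexpected CSV header {header[:3]!r}, "
                f"expected {_CSV_BASE_HEADER!r}",
                line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t_ms.append(int(row[0]))
                dx.append(int(row[1]))
                dy.append(int(row[2]))
            except (ValueError, IndexError) as e:
                raise FormatError(f"malformed CSV row {row!r}", line=lineno) from e
    return EventStream(
        device=device,
        t_ms=np.asarray(t_ms, dtype=np.int64),
        dx=np.asarray(dx, dtype=np.int64),
        dy=np.asarray(dy, dtype=np.int64),
    )
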