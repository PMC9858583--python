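"""Reading and writing time series and dataset manifests.

Two input layouts are accepted: plain text with one sample per line,
and single-column CSV with an optional one-field header.  Blank lines
are skipped; any unparseable or non-finite sample aborts with the
offending line number.  Series are written back with ``repr``
round-trip precision so a write/read cycle is exact.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .core import as_series

__all__ = ["read_series", "write_series", "read_manifest", "write_manifest"]


class SeriesFormatError(ValueError):
    """A series file contains an unparseable or non-finite sample."""


def read_series(path) -> np.ndarray:
    """Read a univariate series from plain text or single-column CSV.

    One float per line; a single non-numeric first line is treated as a
    header.  Lines may carry a trailing comma (single-column CSV
    exports).  NaN and infinities are rejected.
    """
    path = Path(path)
    values: List[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().rstrip(",").strip()
            if not token:
                continue
            try:
                value = float(token)
            except ValueError:
                if lineno == 1 and not values:  # header row
                    continue
                raise SeriesFormatError(
                    f"{path}:{lineno}: cannot parse {token!r} as a sample"
                ) from None
            if not math.isfinite(value):
                raise SeriesFormatError(f"{path}:{lineno}: non-finite sample {token!r}")
            values.append(value)
    if len(values) < 2:
        raise SeriesFormatError(f"{path}: needs at least 2 samples, found {len(values)}")
    return as_series(values)


def write_series(path, x) -> None:
    """Write a series one sample per line at full round-trip precision."""
    arr = as_series(x)
    Path(path).write_text("".join(f"{v!r}\n" for v in arr.tolist()))


def read_manifest(path) -> List[Tuple[str, int]]:
    """Read a ``filename,class`` manifest CSV (header optional)."""
    rows: List[Tuple[str, int]] = []
    with Path(path).open(newline="") as fh:
        for record in csv.reader(fh):
            if not record or not record[0].strip():
                continue
            name, label = record[0].strip(), record[1].strip()
            if not rows and not label.lstrip("-").isdigit():
                continue  # header
            rows.append((name, int(label)))
    if not rows:
        raise SeriesFormatError(f"{path}: empty manifest")
    return rows


def write_manifest(path, entries: Dict[str, int] | List[Tuple[str, int]]) -> None:
    """Write a ``filename,class`` manifest CSV with header."""
    items = entries.items() if isinstance(entries, dict) else entries
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class"])
        for name, label in items:
            writer.writerow([name, label])
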