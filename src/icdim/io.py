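"""Delimited-text matrix I/O (one row per channel)."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .simulate import SignalMatrix

__all__ = ["read_matrix", "write_matrix"]


def read_matrix(
    path: str | Path, delimiter: str = ",", header: bool = False
) -> SignalMatrix:
    """Read a p x n signal matrix from delimited text.

    Rows are channels.  With ``header=True`` the first line lists the p
    channel labels, one per subsequent row — the layout `write_matrix`
    emits — otherwise the file is purely numeric.  Ragged rows or
    non-numeric cells raise with the offending row/column location.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]
    if not rows:
        raise ValueError(f"{path}: empty file")
    labels: list[str] | None = None
    if header:
        labels = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width))
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1 + int(header)} "
                f"({len(r)} cells, expected {width})"
            )
        for j, cell in enumerate(r):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row "
                    f"{i + 1 + int(header)}, column {j + 1}: {cell!r}"
                ) from None
    if labels is not None and len(labels) != len(rows):
        raise ValueError(
            f"{path}: {len(labels)} header labels for {len(rows)} rows"
        )
    return SignalMatrix(data=data, channel_labels=labels)


def write_matrix(
    X: SignalMatrix, path: str | Path, delimiter: str = ",", header: bool = False
) -> None:
    """Write a signal matrix as delimited text, full round-trip precision.

    With ``header=True`` a first line of channel labels is written (one
    label per channel; generated as ``ch1..chp`` when the matrix carries
    none).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header:
            labels = X.channel_labels or [f"ch{i + 1}" for i in range(X.p)]
            fh.write(delimiter.join(labels) + "\n")
        for row in X.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")
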