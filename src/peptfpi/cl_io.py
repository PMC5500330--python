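"""Read, write and time-slice list-mode coincidence-line (CL) data.

The on-disk format is plain whitespace-delimited text, one coincidence
event per row, seven columns: time mark in ms, then x, y, z of the first
detector crystal and x, y, z of the second, all in mm.  Blank lines and
lines starting with ``#`` are skipped; extra trailing columns are ignored.
Timestamps are stored as integer milliseconds so window arithmetic is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "CoincidenceLine",
    "CLStream",
    "CLParseError",
    "read_cl_file",
    "write_cl_file",
    "select_window",
]


class CLParseError(ValueError):
    """Raised when a list-mode file contains a malformed row."""


class CoincidenceLine(NamedTuple):
    """One coincidence event: timestamp plus the two crystal endpoints."""

    t_ms: int
    p1: np.ndarray  # (3,) mm
    p2: np.ndarray  # (3,) mm


@dataclass
class CLStream:
    """An ordered collection of coincidence lines.

    Events are kept in structure-of-arrays form (``t_ms`` int64, endpoint
    arrays of shape ``(n, 3)``) and are always sorted non-decreasing in
    time.  ``t_start_ms``/``t_end_ms`` are the scan bounds; every event
    time lies within them.
    """

    t_ms: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    t_start_ms: int = 0
    t_end_ms: int = 0

    @classmethod
    def from_arrays(
        cls,
        t_ms,
        p1,
        p2,
        t_start_ms: int | None = None,
        t_end_ms: int | None = None,
    ) -> "CLStream":
        """Build a stream, stably sorting events by time.

        Bounds default to the min/max event time (0/0 for an empty
        stream).
        """
        t_ms = np.asarray(t_ms, dtype=np.int64).reshape(-1)
        p1 = np.asarray(p1, dtype=float).reshape(-1, 3)
        p2 = np.asarray(p2, dtype=float).reshape(-1, 3)
        if not (len(t_ms) == len(p1) == len(p2)):
            raise ValueError("t_ms, p1, p2 must have equal lengths")
        if len(t_ms) and t_ms.min() < 0:
            raise ValueError("event times must be non-negative")
        if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
            raise ValueError("crystal coordinates must be finite")
        if len(t_ms) and np.all(p1 == p2, axis=1).any():
            raise ValueError("coincidence line endpoints must differ")
        order = np.argsort(t_ms, kind="stable")
        t_ms, p1, p2 = t_ms[order], p1[order], p2[order]
        if t_start_ms is None:
            t_start_ms = int(t_ms[0]) if len(t_ms) else 0
        if t_end_ms is None:
            t_end_ms = int(t_ms[-1]) if len(t_ms) else 0
        return cls(t_ms, p1, p2, int(t_start_ms), int(t_end_ms))

    def __len__(self) -> int:
        return len(self.t_ms)

    def __iter__(self) -> Iterator[CoincidenceLine]:
        for i in range(len(self)):
            yield self.line(i)

    def line(self, i: int) -> CoincidenceLine:
        return CoincidenceLine(int(self.t_ms[i]), self.p1[i], self.p2[i])


def read_cl_file(path) -> CLStream:
    """Parse a list-mode CL text file into a :class:`CLStream`.

    Raises :class:`CLParseError` naming the offending line number on a
    malformed row.  An empty file yields an empty stream with zero bounds.
    """
    path = Path(path)
    times: list[int] = []
    e1: list[list[float]] = []
    e2: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 7:
                raise CLParseError(
                    f"{path}: line {lineno}: expected >=7 fields, got {len(parts)}"
                )
            try:
                vals = [float(x) for x in parts[:7]]
            except ValueError as exc:
                raise CLParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            times.append(int(round(vals[0])))
            e1.append(vals[1:4])
            e2.append(vals[4:7])
    if not times:
        return CLStream.from_arrays(
            np.empty(0, np.int64), np.empty((0, 3)), np.empty((0, 3))
        )
    return CLStream.from_arrays(times, e1, e2)


def write_cl_file(stream: CLStream, path) -> None:
    """Write a stream in the seven-column list-mode dialect."""
    with open(path, "w") as fh:
        for i in range(len(stream)):
            x1, y1, z1 = stream.p1[i]
            x2, y2, z2 = stream.p2[i]
            fh.write(
                f"{int(stream.t_ms[i])} "
                f"{x1:.6f} {y1:.6f} {z1:.6f} "
                f"{x2:.6f} {y2:.6f} {z2:.6f}\n"
            )


def select_window(stream: CLStream, start_s: float, length_s: float) -> CLStream:
    """Return the events in the half-open interval [start, start+length).

    Boundary events at exactly ``start+length`` are excluded, so adjacent
    windows never double-count.  A window outside the scan yields an empty
    stream.
    """
    if length_s <= 0:
        raise ValueError("window length must be positive")
    lo_ms = int(round(start_s * 1000))
    hi_ms = int(round((start_s + length_s) * 1000))
    i0 = int(np.searchsorted(stream.t_ms, lo_ms, side="left"))
    i1 = int(np.searchsorted(stream.t_ms, hi_ms, side="left"))
    return CLStream(
        stream.t_ms[i0:i1].copy(),
        stream.p1[i0:i1].copy(),
        stream.p2[i0:i1].copy(),
        lo_ms,
        hi_ms,
    )
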