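"""Reading and writing PoPoolation2-style "sync" allele-count tables.

A sync file is tab-separated with one row per genomic site::

    chrom  pos  ref  A:T:C:G:N:del  A:T:C:G:N:del  ...

``pos`` is 1-based and each pool column carries six colon-separated
non-negative integer counts (A, T, C, G, N, deletion).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

BASES = ("A", "T", "C", "G", "N", "del")

__all__ = ["SyncRecord", "SyncParseError", "read_sync", "write_sync", "BASES"]


class SyncParseError(ValueError):
    """Malformed sync input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SyncRecord:
    """One genomic site with per-pool base counts.

    ``counts`` has shape (n_pools, 6) in A,T,C,G,N,del order.
    """

    chrom: str
    pos: int
    ref: str
    counts: tuple  # tuple of per-pool 6-tuples of ints

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for pool in self.counts:
            if len(pool) != 6:
                raise ValueError("each pool needs exactly 6 counts (A:T:C:G:N:del)")
            if any(c < 0 for c in pool):
                raise ValueError("counts must be non-negative")

    @property
    def n_pools(self) -> int:
        return len(self.counts)

    def count_matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _open(path_or_handle, mode: str):
    if isinstance(path_or_handle, (str, Path)):
        return open(path_or_handle, mode), True
    return path_or_handle, False


def read_sync(path: Union[str, Path, TextIO]) -> Iterator[SyncRecord]:
    """Stream :class:`SyncRecord` rows from a sync file.

    Raises :class:`SyncParseError` naming the offending line on malformed
    input (wrong column arity, non-integer counts, pool fields without
    exactly six values).
    """
    handle, owned = _open(path, "rt")
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"expected >= 4 tab-separated columns, got {len(fields)}", lineno
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"position {pos_s!r} is not an integer", lineno)
            pools = []
            for field in fields[3:]:
                parts = field.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"pool field {field!r} has {len(parts)} values, expected 6",
                        lineno,
                    )
                try:
                    pools.append(tuple(int(x) for x in parts))
                except ValueError:
                    raise SyncParseError(f"non-integer count in {field!r}", lineno)
            try:
                yield SyncRecord(chrom=chrom, pos=pos, ref=ref, counts=tuple(pools))
            except ValueError as exc:
                raise SyncParseError(str(exc), lineno)
    finally:
        if owned:
            handle.close()


def format_sync_record(rec: SyncRecord) -> str:
    pools = "\t".join(":".join(str(c) for c in pool) for pool in rec.counts)
    return f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{pools}"


def write_sync(records: Iterable[SyncRecord], path: Union[str, Path, TextIO]) -> None:
    """Write records to a header-free sync file.

    Records must be sorted by (chrom, pos); unsorted input is rejected so the
    on-disk table is always scan-ready. Lossless round-trip with
    :func:`read_sync`.
    """
    handle, owned = _open(path, "wt")
    try:
        last = None
        for rec in records:
            key = (rec.chrom, rec.pos)
            if last is not None and rec.chrom == last[0] and rec.pos <= last[1]:
                raise ValueError(
                    f"records not sorted: {key} after {last} (same chromosome)"
                )
            last = key
            handle.write(format_sync_record(rec) + "\n")
    finally:
        if owned:
            handle.close()


def records_to_string(records: Sequence[SyncRecord]) -> str:
    buf = io.StringIO()
    write_sync(records, buf)
    return buf.getvalue()
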