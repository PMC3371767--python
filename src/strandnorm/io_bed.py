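"""BED input/output and strand-specific read-start count tracks.

All coordinates follow the BED convention: 0-based, half-open intervals.
A read is reduced to a single read-length-independent coordinate, its
biological 5' terminus: ``start`` for a sense (+) read and ``end - 1`` for
an antisense (−) read. These start positions — not coverage pile-ups — are
what the normalization operates on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID_STRANDS = frozenset({"+", "-"})


class BedFormatError(ValueError):
    """A malformed line in a BED file; the message names the line number."""


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequencing read as a stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.chrom}:{self.start}-{self.end}: requires 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_position(self) -> int:
        """The 5' terminus: ``start`` for +, ``end - 1`` for − (half-open)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class StartCountTrack:
    """Per-bp, per-strand counts of read start positions over a region."""

    chrom: str
    origin: int
    counts_sense: np.ndarray
    counts_antisense: np.ndarray

    def __post_init__(self) -> None:
        self.counts_sense = np.asarray(self.counts_sense)
        self.counts_antisense = np.asarray(self.counts_antisense)
        if self.counts_sense.shape != self.counts_antisense.shape:
            raise ValueError("sense and antisense count arrays must have equal length")

    @property
    def length(self) -> int:
        return int(self.counts_sense.shape[0])

    def counts(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.counts_sense
        if strand == "-":
            return self.counts_antisense
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass
class ResidualTrack:
    """Per-bp residual signal per strand, anchored at ``origin``."""

    chrom: str
    origin: int
    sense: np.ndarray
    antisense: np.ndarray

    def __post_init__(self) -> None:
        self.sense = np.asarray(self.sense, dtype=float)
        self.antisense = np.asarray(self.antisense, dtype=float)
        if self.sense.shape != self.antisense.shape:
            raise ValueError("sense and antisense residual arrays must have equal length")


def _parse_bed_line(
    fields: Sequence[str], lineno: int, assume_sense: bool
) -> AlignedRead:
    if len(fields) >= 6:
        chrom, start_s, end_s, strand = fields[0], fields[1], fields[2], fields[5]
    elif len(fields) == 3:
        if not assume_sense:
            raise BedFormatError(
                f"line {lineno}: 3-column BED has no strand; "
                "pass assume_sense=True to default to '+'"
            )
        warnings.warn(
            f"line {lineno}: no strand column, assuming '+'", stacklevel=3
        )
        chrom, start_s, end_s, strand = fields[0], fields[1], fields[2], "+"
    else:
        raise BedFormatError(
            f"line {lineno}: expected 3 or >= 6 tab-separated columns, got {len(fields)}"
        )

    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise BedFormatError(
            f"line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
        ) from None
    if start >= end:
        raise BedFormatError(f"line {lineno}: start >= end ({start} >= {end})")
    if start < 0:
        raise BedFormatError(f"line {lineno}: negative start coordinate {start}")
    if strand == ".":
        if not assume_sense:
            raise BedFormatError(
                f"line {lineno}: strand is '.'; strand is required "
                "(pass assume_sense=True to map it to '+')"
            )
        warnings.warn(f"line {lineno}: strand '.' mapped to '+'", stacklevel=3)
        strand = "+"
    if strand not in _VALID_STRANDS:
        raise BedFormatError(f"line {lineno}: strand not in {{+,-,.}}: {strand!r}")
    return AlignedRead(chrom, start, end, strand)


def read_aligned_reads(
    path: str | Path,
    region: Optional[Region] = None,
    assume_sense: bool = False,
) -> list[AlignedRead]:
    """Read aligned reads from a BED file, in order of appearance.

    Parameters
    ----------
    path
        BED file with >= 6 columns (BED6) or exactly 3 (BED3; strand then
        defaults to '+' only if ``assume_sense``, with a warning).
    region
        Optional filter; only reads overlapping ``region`` are returned.
    assume_sense
        Permit missing ('.' or absent) strand, mapping it to '+'.

    Raises
    ------
    BedFormatError
        On any malformed line, naming its line number.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            read = _parse_bed_line(line.split("\t"), lineno, assume_sense)
            if region is not None:
                if read.chrom != region.chrom:
                    continue
                if read.end <= region.start or read.start >= region.end:
                    continue
            reads.append(read)
    return reads


def extract_start_counts(
    reads: Iterable[AlignedRead], region: Region
) -> StartCountTrack:
    """Count read start positions (5' termini) per bp and strand over a region.

    A + read increments the sense track at ``read.start``; a − read
    increments the antisense track at ``read.end - 1``. Reads whose start
    position falls outside the region are dropped (counted in a log line);
    reads on another chromosome raise.
    """
    sense = np.zeros(region.length, dtype=np.int64)
    antisense = np.zeros(region.length, dtype=np.int64)
    dropped = 0
    for read in reads:
        if read.chrom != region.chrom:
            raise ValueError(
                f"read on {read.chrom} does not match region chromosome {region.chrom}"
            )
        pos = read.start_position
        if not (region.start <= pos < region.end):
            dropped += 1
            continue
        if read.strand == "+":
            sense[pos - region.start] += 1
        else:
            antisense[pos - region.start] += 1
    if dropped:
        logger.info(
            "extract_start_counts: dropped %d reads with start position outside "
            "%s:%d-%d", dropped, region.chrom, region.start, region.end,
        )
    return StartCountTrack(region.chrom, region.start, sense, antisense)


def _dummy_read_interval(pos: int, strand: str, read_length: int) -> tuple[int, int]:
    """BED interval of a dummy read whose extracted start position is ``pos``."""
    if strand == "+":
        return pos, pos + read_length
    return pos - read_length + 1, pos + 1


def write_residual_reads(
    track: ResidualTrack | Sequence[ResidualTrack],
    read_length: int,
    path: str | Path,
) -> int:
    """Write positive regression residuals as BED6 dummy reads.

    Every position ``i`` with residual ``r > 1`` yields ``floor(r)``
    identical dummy reads of ``read_length`` bp anchored so that extracting
    start counts from the output recovers the floored residual at ``i``
    exactly. Output is tab-separated BED6, sorted by (chrom, start), score 0.

    Accepts one track or several (e.g. one per chromosome).
    Returns the number of reads written.
    """
    if read_length < 1:
        raise ValueError(f"read_length must be >= 1, got {read_length}")
    tracks = [track] if isinstance(track, ResidualTrack) else list(track)
    for trk in tracks:
        for arr in (trk.sense, trk.antisense):
            if not np.all(np.isfinite(arr)):
                raise ValueError("residual values must be finite")

    records: list[tuple[str, int, int, str]] = []  # (chrom, start, end, line)
    clipped = 0
    for trk in tracks:
        for strand, values in (("+", trk.sense), ("-", trk.antisense)):
            (hot,) = np.nonzero(values > 1.0)
            for idx in hot:
                pos = trk.origin + int(idx)
                count = int(np.floor(values[idx]))
                start, end = _dummy_read_interval(pos, strand, read_length)
                if start < 0:
                    clipped += 1
                    start = 0
                for k in range(count):
                    name = f"norm_{strand}_{pos}_{k}"
                    line = f"{trk.chrom}\t{start}\t{end}\t{name}\t0\t{strand}"
                    records.append((trk.chrom, start, end, line))
    if clipped:
        warnings.warn(
            f"{clipped} antisense dummy-read positions clipped at coordinate 0"
        )
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w", newline="\n") as fh:
        for _, _, _, line in records:
            fh.write(line + "\n")
    return len(records)
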