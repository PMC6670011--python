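"""Read quality trimming and panel-aware amplicon assignment.

Single-end reads are quality trimmed with trimmomatic-style rules (leading /
trailing base quality, 4-base sliding window, minimum length) and then
assigned to their source amplicon by banded edit distance against every panel
amplicon on both strands.  Because the target space is a small known panel,
mapping ambiguity reduces to a best-vs-second-best comparison: a read is kept
only if its best hit is unique by a margin of at least ``min_margin`` edits,
the panel-aware analogue of a mapping-quality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Iterator, Optional, Union

import edlib
import numpy as np
from Bio import SeqIO

from .panel import AmpliconPanel, revcomp

__all__ = ["ReadRecord", "AssignedRead", "read_fastq", "trim_read", "assign_read"]


@dataclass(frozen=True)
class ReadRecord:
    """A single-end read with phred33 base qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.read_id!r}: bases/quals length mismatch")
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise ValueError(f"read {self.read_id!r}: phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "ReadRecord":
        return ReadRecord(
            self.read_id, self.bases[start:stop], self.quals[start:stop], self.sample_id
        )


@dataclass(frozen=True)
class AssignedRead:
    """A read placed on its best-matching amplicon.

    ``bases``/``quals`` are stored in amplicon-strand orientation so that
    pileup construction never needs to re-orient.  ``offset`` is the 1-based
    alignment start on the amplicon; ``cigar`` is an extended cigar (= X I D)
    of read against amplicon.
    """

    read_id: str
    sample_id: str
    amplicon: str
    offset: int
    strand: str
    edit_distance: int
    assignment_margin: int
    cigar: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.edit_distance < 0 or self.assignment_margin < 0:
            raise ValueError("edit_distance and assignment_margin must be >= 0")


def read_fastq(
    path: Union[str, Path], sample_id: str = ""
) -> Iterator[ReadRecord]:
    """Iterate phred33 FASTQ records as :class:`ReadRecord`."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
            sample_id,
        )


def trim_read(
    read: ReadRecord,
    end_q: int = 15,
    window: int = 4,
    window_q: float = 15,
    min_len: int = 70,
) -> Optional[ReadRecord]:
    """Quality-trim a read; returns ``None`` when the read is discarded.

    Rules, in order: (1) drop leading bases with q < ``end_q``; (2) drop
    trailing bases with q < ``end_q``; (3) scan 5'->3' and cut the read at the
    first ``window``-base window whose mean quality is < ``window_q`` (the
    trailing-quality rule is re-applied after the cut so trimming is
    idempotent); (4) discard if fewer than ``min_len`` bases remain.
    """
    q = np.asarray(read.quals, dtype=float)
    start, stop = 0, len(q)
    while start < stop and q[start] < end_q:
        start += 1
    while stop > start and q[stop - 1] < end_q:
        stop -= 1
    if stop - start >= window:
        w = np.convolve(q[start:stop], np.ones(window) / window, mode="valid")
        below = np.nonzero(w < window_q)[0]
        if below.size:
            stop = start + int(below[0])
            while stop > start and q[stop - 1] < end_q:
                stop -= 1
    if stop - start < min_len:
        return None
    return read.slice(start, stop)


def _distance(query: str, target: str, k: int) -> int:
    """Infix edit distance of query against target, capped at k + 1."""
    d = edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]
    return k + 1 if d == -1 else d


def assign_read(
    read: ReadRecord,
    panel: AmpliconPanel,
    max_edit_frac: float = 0.10,
    min_margin: int = 2,
) -> Optional[AssignedRead]:
    """Assign a trimmed read to the unique best-matching panel amplicon.

    The read is compared against every amplicon on both strands with a banded
    (infix) edit distance.  It is assigned iff the best distance is at most
    ``ceil(max_edit_frac * len(read))`` and the second-best amplicon is at
    least ``min_margin`` edits worse; otherwise ``None`` (unassigned).
    """
    if len(read) == 0:
        return None
    max_dist = ceil(max_edit_frac * len(read))
    k = max_dist + min_margin  # enough band to resolve the margin rule
    rc_bases = revcomp(read.bases)
    best: list[tuple[int, str, str]] = []  # (distance, amplicon, strand)
    for amp in panel:
        d_fwd = _distance(read.bases, amp.sequence, k)
        d_rev = _distance(rc_bases, amp.sequence, k)
        if d_fwd <= d_rev:
            best.append((d_fwd, amp.name, "+"))
        else:
            best.append((d_rev, amp.name, "-"))
    best.sort(key=lambda t: (t[0], t[1]))
    d0, name, strand = best[0]
    d1 = best[1][0] if len(best) > 1 else k + 1
    margin = d1 - d0
    if d0 > max_dist or margin < min_margin:
        return None
    oriented = read.bases if strand == "+" else rc_bases
    oriented_q = read.quals if strand == "+" else read.quals[::-1]
    aln = edlib.align(oriented, panel[name].sequence, mode="HW", task="path", k=k)
    t_start = aln["locations"][0][0]
    return AssignedRead(
        read_id=read.read_id,
        sample_id=read.sample_id,
        amplicon=name,
        offset=t_start + 1,
        strand=strand,
        edit_distance=d0,
        assignment_margin=margin,
        cigar=aln["cigar"],
        bases=oriented,
        quals=tuple(oriented_q),
    )


def assigned_to_frame(assigned: list[AssignedRead]):
    """Tabulate assignments as a SAM-like debug table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "sample": a.sample_id,
                "amplicon": a.amplicon,
                "offset": a.offset,
                "strand": a.strand,
                "edit_distance": a.edit_distance,
                "margin": a.assignment_margin,
            }
            for a in assigned
        ]
    )
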