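"""Per-position base counting and allele-frequency computation.

Assigned reads are piled up per (sample, amplicon, offset); only bases with
phred quality >= 30 contribute to either the allele counts or the depth.
Simple indels are carried as composite allele keys ("+SEQ" for insertions,
"-N" for deletions) left-anchored at the last aligned base, VCF style.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .panel import AmpliconPanel, amplicon_to_genome, plus_strand_allele
from .reads import AssignedRead

__all__ = [
    "PileupColumn",
    "VariantObservation",
    "build_pileup",
    "compute_af",
    "count_table",
    "observations_from_table",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: columns of the canonical count-table exchange format
COUNT_TABLE_COLUMNS = [
    "sample",
    "amplicon",
    "offset",
    "chrom",
    "pos",
    "ref",
    "allele",
    "count",
    "depth",
]


@dataclass
class PileupColumn:
    """Base counts at one (sample, amplicon, offset).

    Alleles are in amplicon-strand orientation; ``depth`` is the number of
    qualifying (phred >= threshold) read observations and always equals the
    sum of the counts.
    """

    sample_id: str
    amplicon: str
    offset: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def add(self, allele: str, n: int = 1) -> None:
        self.counts[allele] = self.counts.get(allele, 0) + n


@dataclass(frozen=True)
class VariantObservation:
    """One non-reference allele observed in one sample at one position."""

    sample_id: str
    amplicon: str
    offset: int
    allele: str
    count: int
    depth: int
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.count <= self.depth:
            raise ValueError("require 1 <= count <= depth")

    @property
    def af(self) -> float:
        return self.count / self.depth


def build_pileup(
    assigned: Iterable[AssignedRead],
    panel: AmpliconPanel,
    min_base_q: int = 30,
    mask_primers: bool = True,
) -> list[PileupColumn]:
    """Pile up assigned reads into per-position allele counts.

    Bases below ``min_base_q`` are excluded from both the counts and the
    depth; N bases are dropped entirely.  With primer masking on, offsets in
    the primer-binding regions are omitted.
    """
    columns: dict[tuple[str, str, int], PileupColumn] = {}

    def col(sample: str, amp_name: str, offset: int) -> PileupColumn:
        key = (sample, amp_name, offset)
        if key not in columns:
            columns[key] = PileupColumn(
                sample, amp_name, offset, panel[amp_name].base_at(offset)
            )
        return columns[key]

    allowed: dict[str, range] = {
        a.name: a.insert_offsets(mask_primers) for a in panel
    }
    for read in assigned:
        rng = allowed[read.amplicon]
        tpos = read.offset - 1  # 0-based on amplicon
        qpos = 0
        for n_str, op in _CIGAR_RE.findall(read.cigar):
            n = int(n_str)
            if op in "=X":
                for i in range(n):
                    off = tpos + i + 1
                    base = read.bases[qpos + i]
                    if off in rng and base != "N" and read.quals[qpos + i] >= min_base_q:
                        col(read.sample_id, read.amplicon, off).add(base)
                tpos += n
                qpos += n
            elif op == "I":
                anchor = max(tpos, 1)  # left-anchored at last aligned base
                seq = read.bases[qpos : qpos + n]
                quals = read.quals[qpos : qpos + n]
                if anchor in rng and "N" not in seq and min(quals) >= min_base_q:
                    col(read.sample_id, read.amplicon, anchor).add("+" + seq)
                qpos += n
            elif op == "D":
                anchor = max(tpos, 1)
                flank_q = read.quals[qpos - 1] if qpos > 0 else read.quals[qpos]
                if anchor in rng and flank_q >= min_base_q:
                    col(read.sample_id, read.amplicon, anchor).add(f"-{n}")
                tpos += n
    order = {name: i for i, name in enumerate(panel.names)}
    return sorted(
        columns.values(), key=lambda c: (c.sample_id, order[c.amplicon], c.offset)
    )


def compute_af(column: PileupColumn) -> list[VariantObservation]:
    """Allele frequencies of every non-reference allele in a pileup column.

    AF is the variant-supporting read count divided by the qualifying depth
    at the position.  Zero-depth columns yield no observations.
    """
    if column.depth == 0:
        return []
    return [
        VariantObservation(
            sample_id=column.sample_id,
            amplicon=column.amplicon,
            offset=column.offset,
            allele=allele,
            count=n,
            depth=column.depth,
        )
        for allele, n in sorted(column.counts.items())
        if allele != column.ref_base and n >= 1
    ]


def count_table(
    columns: Iterable[PileupColumn], panel: AmpliconPanel
) -> pd.DataFrame:
    """Materialize pileup columns as the canonical count-table DataFrame.

    One row per non-reference allele with count >= 1.  ``ref`` and ``allele``
    are reported on the genomic plus strand; ``offset`` stays amplicon-local
    (it is the position covariate of the noise model).
    """
    rows = []
    for column in columns:
        amp = panel[column.amplicon]
        chrom, pos = amplicon_to_genome(panel, column.amplicon, column.offset)
        ref_plus = plus_strand_allele(amp, column.ref_base)
        for obs in compute_af(column):
            rows.append(
                {
                    "sample": obs.sample_id,
                    "amplicon": obs.amplicon,
                    "offset": obs.offset,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref_plus,
                    "allele": plus_strand_allele(amp, obs.allele),
                    "count": obs.count,
                    "depth": obs.depth,
                }
            )
    return pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)


def observations_from_table(
    table: pd.DataFrame, min_depth: int = 100
) -> pd.DataFrame:
    """Filter a count table to model-ready observations and add ``af``.

    Columns below ``min_depth`` qualifying reads are dropped: their allele
    fractions are dominated by counting noise and destabilize the logit-scale
    fit.
    """
    obs = table.loc[(table["depth"] >= min_depth) & (table["count"] >= 1)].copy()
    obs["af"] = obs["count"] / obs["depth"]
    return obs.reset_index(drop=True)
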