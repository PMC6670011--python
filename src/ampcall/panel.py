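"""Amplicon panel model: loading, genome anchoring and coordinate translation.

An amplicon panel is a small (typically tens of entries) set of PCR products
targeting mutational hotspots.  Each amplicon is anchored to a reference
genome by exact (100% identity) substring search on both strands; after
anchoring, positions translate bijectively between genomic coordinates and
1-based offsets along the amplicon's own 5'->3' sequence.

Coordinates are 1-based and fully closed throughout, matching VCF/COSMIC
conventions.  Variant alleles are always reported on the genomic plus strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "CatalogueEntry",
    "Catalogue",
    "PanelError",
    "AnchoringError",
    "load_panel",
    "load_reference",
    "anchor_amplicons",
    "genome_to_amplicon",
    "amplicon_to_genome",
    "load_catalogue",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: expected amplicon insert size range for this assay design
LENGTH_RANGE = (100, 175)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Malformed panel or catalogue input."""


class AnchoringError(PanelError):
    """An amplicon could not be uniquely placed on the reference."""


@dataclass(frozen=True)
class Amplicon:
    """One amplicon: its insert sequence and, once anchored, genomic placement.

    ``start`` is the 1-based plus-strand genomic coordinate of the leftmost
    base of the amplicon region regardless of strand; ``strand`` records the
    orientation of the amplicon sequence relative to the reference.
    """

    name: str
    sequence: str
    pool: int = 0
    fwd_primer_len: int = 0
    rev_primer_len: int = 0
    chrom: Optional[str] = None
    start: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("amplicon name must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - set("ACGT"):
            raise PanelError(
                f"amplicon {self.name!r}: sequence must be non-empty ACGT only"
            )
        if not (LENGTH_RANGE[0] <= len(seq) <= LENGTH_RANGE[1]):
            warnings.warn(
                f"amplicon {self.name!r} length {len(seq)} outside expected "
                f"range {LENGTH_RANGE[0]}-{LENGTH_RANGE[1]} nt",
                stacklevel=2,
            )
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise PanelError(f"amplicon {self.name!r}: negative primer length")
        if self.fwd_primer_len + self.rev_primer_len >= len(seq):
            raise PanelError(f"amplicon {self.name!r}: primers cover whole insert")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> Optional[int]:
        """1-based inclusive genomic end, once anchored."""
        if self.start is None:
            return None
        return self.start + self.length - 1

    @property
    def is_anchored(self) -> bool:
        return self.chrom is not None and self.start is not None

    def insert_offsets(self, mask_primers: bool = True) -> range:
        """1-based amplicon offsets eligible for variant calling.

        With primer masking on, the first ``fwd_primer_len`` and the last
        ``rev_primer_len`` bases are excluded: primer-derived bases are
        synthetic and cannot carry template variants.
        """
        if mask_primers:
            return range(self.fwd_primer_len + 1, self.length - self.rev_primer_len + 1)
        return range(1, self.length + 1)

    def base_at(self, offset: int) -> str:
        """Amplicon-strand base at a 1-based offset."""
        return self.sequence[offset - 1]


@dataclass
class AmpliconPanel:
    """Ordered collection of uniquely named amplicons."""

    amplicons: list[Amplicon]
    version: str = ""
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate amplicon names: {sorted(dupes)}")
        for amp in self.amplicons:
            # a self-reverse-complementary amplicon would anchor to both
            # strands at once and break strand assignment downstream
            if amp.sequence == revcomp(amp.sequence):
                raise PanelError(f"amplicon {amp.name!r} is palindromic")
        self._by_name = {a.name: a for a in self.amplicons}

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    @property
    def is_anchored(self) -> bool:
        return all(a.is_anchored for a in self.amplicons)


def load_panel(path: Union[str, Path], version: str = "") -> AmpliconPanel:
    """Read an amplicon panel from a TSV file.

    Expected header: ``name  sequence  pool  fwd_primer_len  rev_primer_len``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "sequence"}
    if missing := required - set(df.columns):
        raise PanelError(f"{path}: missing panel columns {sorted(missing)}")
    amplicons = []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after the header
        try:
            amplicons.append(
                Amplicon(
                    name=str(row["name"]),
                    sequence=str(row["sequence"]),
                    pool=int(row.get("pool", 0) or 0),
                    fwd_primer_len=int(row.get("fwd_primer_len", 0) or 0),
                    rev_primer_len=int(row.get("rev_primer_len", 0) or 0),
                )
            )
        except PanelError as err:
            raise PanelError(f"{path} line {line_no}: {err}") from err
    return AmpliconPanel(amplicons, version=version or path.stem)


def load_reference(path: Union[str, Path]) -> dict[str, str]:
    """Load a FASTA reference as a {chrom: sequence} mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence starts of needle in haystack (overlaps allowed)."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def anchor_amplicons(
    panel: AmpliconPanel, reference: Union[dict[str, str], str, Path]
) -> AmpliconPanel:
    """Place every amplicon on the reference by exact substring search.

    Both strands are searched; each amplicon must match exactly once genome
    wide (100% sequence identity).  Zero hits or multiple hits abort with the
    amplicon named.  Returns a new, fully anchored panel; anchoring is
    idempotent and independent of amplicon order.
    """
    if not isinstance(reference, dict):
        reference = load_reference(reference)
    anchored = []
    for amp in panel:
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(amp.sequence)
        for chrom, seq in reference.items():
            hits += [(chrom, p + 1, "+") for p in _find_all(seq, amp.sequence)]
            hits += [(chrom, p + 1, "-") for p in _find_all(seq, rc)]
        if not hits:
            raise AnchoringError(f"amplicon {amp.name!r}: no exact match in reference")
        if len(hits) > 1:
            raise AnchoringError(
                f"amplicon {amp.name!r}: ambiguous anchoring ({len(hits)} exact hits)"
            )
        chrom, start, strand = hits[0]
        anchored.append(replace(amp, chrom=chrom, start=start, strand=strand))
    out = AmpliconPanel(anchored, version=panel.version)
    _check_no_overlap(out)
    return out


def _check_no_overlap(panel: AmpliconPanel) -> None:
    by_chrom: dict[str, list[Amplicon]] = {}
    for amp in panel:
        by_chrom.setdefault(amp.chrom, []).append(amp)
    for chrom, amps in by_chrom.items():
        amps = sorted(amps, key=lambda a: a.start)
        for prev, cur in zip(amps, amps[1:]):
            if cur.start <= prev.end:
                raise PanelError(
                    f"amplicons {prev.name!r} and {cur.name!r} overlap on {chrom}"
                )


def genome_to_amplicon(
    panel: AmpliconPanel, chrom: str, pos: int
) -> Optional[tuple[str, int]]:
    """Map a genomic position to (amplicon name, 1-based offset).

    The offset counts along the amplicon's own 5'->3' sequence; for minus
    strand amplicons offset 1 is the rightmost genomic base.  Returns ``None``
    for positions not covered by any amplicon.
    """
    for amp in panel:
        if amp.chrom == chrom and amp.start <= pos <= amp.end:
            if amp.strand == "+":
                return amp.name, pos - amp.start + 1
            return amp.name, amp.end - pos + 1
    return None


def amplicon_to_genome(panel: AmpliconPanel, name: str, offset: int) -> tuple[str, int]:
    """Inverse of :func:`genome_to_amplicon` for in-range offsets."""
    amp = panel[name]
    if not 1 <= offset <= amp.length:
        raise ValueError(f"offset {offset} outside amplicon {name!r} (1..{amp.length})")
    if not amp.is_anchored:
        raise PanelError(f"amplicon {name!r} is not anchored")
    if amp.strand == "+":
        return amp.chrom, amp.start + offset - 1
    return amp.chrom, amp.end - offset + 1


def plus_strand_allele(amp: Amplicon, allele: str) -> str:
    """Convert an amplicon-strand allele to the genomic plus strand.

    Composite indel keys keep their form: the inserted sequence of a "+SEQ"
    allele is reverse complemented on minus-strand amplicons, "-N" deletion
    keys are length-only and unchanged.
    """
    if amp.strand == "+":
        return allele
    if allele.startswith("+"):
        return "+" + revcomp(allele[1:])
    if allele.startswith("-"):
        return allele
    return revcomp(allele)


@dataclass(frozen=True)
class CatalogueEntry:
    """One known-somatic-mutation record (COSMIC-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    variant_id: str = ""
    is_snp: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise PanelError(f"catalogue entry {self.variant_id!r}: ref == alt")
        if self.pos < 1:
            raise PanelError(f"catalogue entry {self.variant_id!r}: pos < 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class Catalogue:
    """Known-mutation catalogue indexed by (chrom, pos, ref, alt)."""

    def __init__(self, entries: list[CatalogueEntry]):
        self.entries = list(entries)
        self._index = {e.key: e for e in self.entries}

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> Optional[CatalogueEntry]:
        return self._index.get((chrom, int(pos), ref, alt))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogueEntry]:
        return iter(self.entries)

    def __contains__(self, key: tuple) -> bool:
        return (key[0], int(key[1]), key[2], key[3]) in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": e.chrom,
                    "pos": e.pos,
                    "ref": e.ref,
                    "alt": e.alt,
                    "gene": e.gene,
                    "variant_id": e.variant_id,
                    "is_snp": "y" if e.is_snp else "n",
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_catalogue(path: Union[str, Path]) -> Catalogue:
    """Read a mutation catalogue from TSV.

    Expected header: ``chrom  pos  ref  alt  gene  variant_id  is_snp``
    with is_snp coded y/n.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if missing := required - set(df.columns):
        raise PanelError(f"{path}: missing catalogue columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                CatalogueEntry(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]),
                    gene=str(row.get("gene", "") or ""),
                    variant_id=str(row.get("variant_id", "") or ""),
                    is_snp=str(row.get("is_snp", "n")).strip().lower() in ("y", "yes", "1", "true"),
                )
            )
        except (PanelError, ValueError) as err:
            raise PanelError(f"{path} line {i + 2}: {err}") from err
    return Catalogue(entries)
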