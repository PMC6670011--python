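"""Catalogue-based annotation of called mutations.

Only variants already known in a somatic-mutation catalogue (COSMIC-style)
are reported; catalogue entries flagged as germline SNPs are excluded.
Matching is allele-exact on (chrom, pos, ref, alt) after left-alignment of
indels, so a different substitution at a shared hotspot position is never
annotated by accident.
"""

from __future__ import annotations

import pandas as pd

from .noise import REASON_NOT_IN_CATALOGUE, REASON_SNP
from .panel import Catalogue

__all__ = ["annotate_and_filter"]


def annotate_and_filter(calls: pd.DataFrame, catalogue: Catalogue) -> pd.DataFrame:
    """Annotate called mutations against the catalogue and drop unknowns.

    Rows with status ``called`` (or ``annotated``, making the operation
    idempotent) that match a non-SNP catalogue entry become ``annotated`` and
    carry the entry's gene and variant id; non-matching rows are rejected
    with reason "not-in-catalogue" and SNP-flagged matches with reason "snp".
    All other rows pass through unchanged; AF, residuals and coordinates are
    never altered.
    """
    out = calls.copy()
    for col, default in (("gene", ""), ("variant_id", "")):
        if col not in out.columns:
            out[col] = default
    candidates = out["status"].isin(("called", "annotated"))
    for idx in out.index[candidates]:
        row = out.loc[idx]
        entry = catalogue.get(row["chrom"], int(row["pos"]), row["ref"], row["allele"])
        if entry is None:
            out.loc[idx, ["status", "reason"]] = ("rejected", REASON_NOT_IN_CATALOGUE)
        elif entry.is_snp:
            out.loc[idx, ["status", "reason"]] = ("rejected", REASON_SNP)
        else:
            out.loc[idx, ["status", "reason"]] = ("annotated", "")
            out.loc[idx, ["gene", "variant_id"]] = (entry.gene, entry.variant_id)
    return out
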