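"""End-to-end calling pipeline: trim -> assign -> pileup -> fit -> call -> annotate.

The pipeline accepts either raw FASTQ files (processed with the built-in
panel-aware assignment stage) or an externally produced per-position count
table (bam-readcount-style TSV), and produces an annotated call table, per-
amplicon fit diagnostics and a stage-by-stage audit log in which every read,
observation and call is accounted for.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import annotate as _annotate
from . import noise as _noise
from .longitudinal import load_sample_sheet, sample_sets, classify_recurrence
from .panel import (
    AmpliconPanel,
    Catalogue,
    anchor_amplicons,
    load_catalogue,
    load_panel,
)
from .pileup import build_pileup, count_table, observations_from_table
from .reads import assign_read, read_fastq, trim_read

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "PipelineResult",
    "call_pipeline_from_counts",
    "process_fastq",
    "run_call_pipeline",
    "write_calls",
]

CALL_COLUMNS = [
    "sample",
    "patient",
    "gene",
    "chrom",
    "pos",
    "ref",
    "allele",
    "af",
    "count",
    "depth",
    "residual",
    "z_excess",
    "status",
    "reason",
    "recurrence",
    "variant_id",
    "amplicon",
    "offset",
]


@dataclass
class PipelineParams:
    """Every threshold of the workflow, defaulted to the assay's values."""

    end_q: int = 15
    window: int = 4
    window_q: float = 15
    min_len: int = 70
    max_edit_frac: float = 0.10
    min_margin: int = 2
    min_base_q: int = 30
    mask_primers: bool = True
    min_depth: int = 100
    sd_threshold: float = 3.0
    min_af: float = 0.005
    loss: str = "huber"
    residual_scale: str = "sd"
    pool_residuals: bool = False


@dataclass
class PipelineConfig:
    """File-level configuration of a pipeline run."""

    panel: str
    catalogue: str
    reference: Optional[str] = None
    sample_sheet: Optional[str] = None
    fastq: dict = field(default_factory=dict)  # sample_id -> path
    counts: Optional[str] = None
    out_dir: str = "ampcall_out"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**(raw.pop("params", {}) or {}))
        return cls(params=params, **raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    fits: dict
    audit: dict
    observations: pd.DataFrame


def process_fastq(
    fastq: dict[str, Union[str, Path]],
    panel: AmpliconPanel,
    params: PipelineParams,
    audit: Optional[dict] = None,
) -> list:
    """Trim and assign reads from per-sample FASTQ files.

    The audit dict receives ``reads_total``, ``reads_discarded_trim``,
    ``reads_unassigned`` and ``reads_assigned``; these always telescope.
    """
    audit = audit if audit is not None else {}
    audit.setdefault("reads_total", 0)
    audit.setdefault("reads_discarded_trim", 0)
    audit.setdefault("reads_unassigned", 0)
    audit.setdefault("reads_assigned", 0)
    per_amplicon: dict[str, int] = audit.setdefault("reads_per_amplicon", {})
    assigned = []
    for sample, path in sorted(fastq.items()):
        for read in read_fastq(path, sample_id=sample):
            audit["reads_total"] += 1
            trimmed = trim_read(
                read,
                end_q=params.end_q,
                window=params.window,
                window_q=params.window_q,
                min_len=params.min_len,
            )
            if trimmed is None:
                audit["reads_discarded_trim"] += 1
                continue
            hit = assign_read(
                trimmed,
                panel,
                max_edit_frac=params.max_edit_frac,
                min_margin=params.min_margin,
            )
            if hit is None:
                audit["reads_unassigned"] += 1
                continue
            audit["reads_assigned"] += 1
            per_amplicon[hit.amplicon] = per_amplicon.get(hit.amplicon, 0) + 1
            assigned.append(hit)
    return assigned


def call_pipeline_from_counts(
    counts: pd.DataFrame,
    panel: AmpliconPanel,
    catalogue: Catalogue,
    sheet: Optional[pd.DataFrame] = None,
    params: Optional[PipelineParams] = None,
    audit: Optional[dict] = None,
) -> PipelineResult:
    """Run model fitting, calling, annotation and recurrence labelling
    on an existing count table."""
    params = params or PipelineParams()
    audit = audit if audit is not None else {}
    obs = observations_from_table(counts, min_depth=params.min_depth)
    audit["count_rows_total"] = int(len(counts))
    audit["count_rows_below_min_depth"] = int(len(counts) - len(obs))
    audit["observations"] = int(len(obs))
    fits, calls = _noise.fit_and_call(
        obs,
        sd_threshold=params.sd_threshold,
        min_af=params.min_af,
        loss=params.loss,
        residual_scale=params.residual_scale,
        pool_residuals=params.pool_residuals,
    )
    audit["raw_variants_per_amplicon"] = (
        obs.groupby("amplicon").size().to_dict() if len(obs) else {}
    )
    audit["called_pre_catalogue"] = int((calls["status"] == "called").sum())
    calls = _annotate.annotate_and_filter(calls, catalogue)
    calls["patient"] = ""
    calls["recurrence"] = ""
    if sheet is not None:
        patient_of = sheet.set_index("sample_id")["patient_id"]
        calls["patient"] = calls["sample"].map(patient_of).fillna("")
        for patient, sset in sample_sets(sheet).items():
            classes = classify_recurrence(sset, calls)
            if not classes:
                continue
            mask = calls["sample"].isin(sset.sample_ids) & (
                calls["status"] == "annotated"
            )
            for idx in calls.index[mask]:
                key = (
                    calls.at[idx, "chrom"],
                    calls.at[idx, "pos"],
                    calls.at[idx, "ref"],
                    calls.at[idx, "allele"],
                )
                calls.at[idx, "recurrence"] = classes.get(key, "")
    audit["annotated"] = int((calls["status"] == "annotated").sum())
    reasons = (
        calls.loc[calls["status"] == "rejected", "reason"].value_counts().to_dict()
    )
    audit["rejected_by_reason"] = {str(k): int(v) for k, v in reasons.items()}
    for col in CALL_COLUMNS:
        if col not in calls.columns:
            calls[col] = ""
    calls = calls[CALL_COLUMNS].sort_values(
        ["sample", "chrom", "pos", "allele"], ignore_index=True
    )
    return PipelineResult(calls=calls, fits=fits, audit=audit, observations=obs)


def run_call_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow described by a configuration.

    Either ``config.fastq`` (per-sample FASTQ files, processed by the
    built-in trim/assign/pileup stages) or ``config.counts`` (an external
    count table) must be given.  Outputs (calls TSV, fit diagnostics TSV and
    the audit log YAML) are written under ``config.out_dir``; the run is
    deterministic given its inputs.
    """
    panel = load_panel(config.panel)
    if config.reference:
        panel = anchor_amplicons(panel, config.reference)
    elif not panel.is_anchored:
        pass  # counts input carries genomic coordinates already
    catalogue = load_catalogue(config.catalogue)
    sheet = load_sample_sheet(config.sample_sheet) if config.sample_sheet else None
    audit: dict = {}
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t")
    elif config.fastq:
        if not panel.is_anchored:
            raise ValueError("FASTQ input requires a reference to anchor the panel")
        assigned = process_fastq(config.fastq, panel, config.params, audit)
        columns = build_pileup(
            assigned,
            panel,
            min_base_q=config.params.min_base_q,
            mask_primers=config.params.mask_primers,
        )
        counts = count_table(columns, panel)
    else:
        raise ValueError("config must name either fastq files or a count table")
    if sheet is not None and len(counts):
        shared = set(sheet["sample_id"]) & set(counts["sample"].astype(str))
        if not shared:
            raise ValueError("no samples shared between sample sheet and data")
    result = call_pipeline_from_counts(
        counts, panel, catalogue, sheet=sheet, params=config.params, audit=audit
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_calls(result.calls, out / "calls.tsv", fmt="tsv")
    write_calls(result.calls, out / "calls.vcf", fmt="vcf", panel=panel)
    _noise.fit_diagnostics(result.fits).to_csv(
        out / "fit_diagnostics.tsv", sep="\t", index=False
    )
    with open(out / "audit.yaml", "w") as fh:
        yaml.safe_dump(result.audit, fh, sort_keys=True)
    return result


def _vcf_ref_alt(row: pd.Series, panel: Optional[AmpliconPanel]) -> tuple[int, str, str]:
    """Convert a call row to VCF POS/REF/ALT, padding composite indel keys."""
    pos, ref, alt = int(row["pos"]), str(row["ref"]), str(row["allele"])
    if alt.startswith("+"):
        return pos, ref, ref + alt[1:]
    if alt.startswith("-"):
        n = int(alt[1:])
        deleted = "N" * n
        if panel is not None and row["amplicon"] in panel:
            amp = panel[row["amplicon"]]
            off = int(row["offset"])
            if amp.strand == "+":
                deleted = amp.sequence[off : off + n]
            else:
                from .panel import revcomp

                seg = amp.sequence[off : off + n]
                deleted = revcomp(seg)
        return pos, ref + deleted, ref
    return pos, ref, alt


def write_calls(
    calls: pd.DataFrame,
    path: Union[str, Path],
    fmt: str = "tsv",
    panel: Optional[AmpliconPanel] = None,
) -> Path:
    """Write the call table as TSV or VCF 4.2.

    The VCF carries one record per (mutation, sample) restricted to
    annotated calls, with AF/DP/AD in FORMAT and the residual z-score in
    INFO; it round-trips through standard VCF parsers.
    """
    path = Path(path)
    if fmt == "tsv":
        calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    ann = calls.loc[calls["status"] == "annotated"].copy()
    samples = sorted(ann["sample"].astype(str).unique())
    contigs: dict[str, int] = {}
    if panel is not None:
        for amp in panel:
            if amp.is_anchored:
                contigs[amp.chrom] = max(contigs.get(amp.chrom, 0), amp.end + 1000)
    for c in ann["chrom"].astype(str).unique():
        contigs.setdefault(c, int(ann.loc[ann["chrom"] == c, "pos"].max()) + 1000)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ampcall",
        '##INFO=<ID=ZEX,Number=1,Type=Float,Description="Noise-model residual z excess over median">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol from catalogue">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (placeholder)">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Qualifying depth">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Variant-supporting reads">',
    ]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in sorted(contigs.items())]
    header_cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header_cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header_cols)
    records: dict[tuple, dict] = {}
    for _, row in ann.iterrows():
        pos, ref, alt = _vcf_ref_alt(row, panel)
        key = (str(row["chrom"]), pos, ref, alt)
        rec = records.setdefault(
            key,
            {
                "id": str(row["variant_id"]) or ".",
                "gene": str(row["gene"]) or ".",
                "zex": float(row["z_excess"]),
                "fmt": {},
            },
        )
        rec["zex"] = max(rec["zex"], float(row["z_excess"]))
        rec["fmt"][str(row["sample"])] = (
            f"0/1:{float(row['af']):.6g}:{int(row['depth'])}:{int(row['count'])}"
        )
    for (chrom, pos, ref, alt), rec in sorted(records.items()):
        fmt_fields = [rec["fmt"].get(s, "./.:.:.:.") for s in samples]
        lines.append(
            f"{chrom}\t{pos}\t{rec['id']}\t{ref}\t{alt}\t.\tPASS\t"
            f"ZEX={rec['zex']:.4g};GENE={rec['gene']}\tGT:AF:DP:AD\t"
            + "\t".join(fmt_fields)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
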