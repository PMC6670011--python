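"""Synthetic amplicon sequencing data with the noise structure the caller assumes.

The generators emulate deep multiplex amplicon sequencing of cell-free DNA:

* per-position PCR error with a mild positional trend on the logit scale,
* per-sample sequencing-error offsets,
* observation-level logit noise,
* negative-binomial sequencing depth spanning roughly 500-21000x at mean
  7500x (matching the depth spread of a 43-amplicon MiSeq panel),
* true variants injected binomially at specified mutant allele fractions.

Every generator is a pure function of its parameters and an explicit seed,
so identical calls produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import (
    Amplicon,
    AmpliconPanel,
    Catalogue,
    CatalogueEntry,
    amplicon_to_genome,
    anchor_amplicons,
    plus_strand_allele,
    revcomp,
)
from .pileup import COUNT_TABLE_COLUMNS

__all__ = [
    "ErrorModel",
    "DepthModel",
    "InjectedVariant",
    "synthetic_panel",
    "synthetic_catalogue",
    "simulate_pileup_counts",
    "simulate_dilution_series",
    "simulate_fastq",
    "simulate_serial_cohort",
]

_BASES = "ACGT"

#: transition-biased substitution weights, ref base -> {alt: weight}
_DEFAULT_BIAS = {
    "A": {"G": 4.0, "C": 1.0, "T": 1.0},
    "C": {"T": 4.0, "A": 1.0, "G": 1.0},
    "G": {"A": 4.0, "C": 1.0, "T": 1.0},
    "T": {"C": 4.0, "A": 1.0, "G": 1.0},
}

_GENES = [
    "TP53", "KRAS", "APC", "PIK3CA", "BRAF", "SMAD4", "NRAS", "FBXW7",
    "TCF7L2", "CTNNB1", "ERBB2", "POLE", "MLH1", "MSH2", "DPYD", "UMPS",
    "TYMS", "EGFR",
]


@dataclass
class ErrorModel:
    """Noise parameters of the simulated assay.

    ``base_rate`` is the mean per-position error fraction; ``beta1_true`` the
    positional trend on the logit scale (per base of amplicon offset);
    ``sample_sd`` the SD of per-sample logit offsets; ``resid_sd`` the SD of
    observation-level logit noise; ``substitution_bias`` the ref->alt error
    spectrum weights.
    """

    base_rate: float = 0.001
    beta1_true: float = 0.005
    sample_sd: float = 0.2
    resid_sd: float = 0.3
    substitution_bias: dict = field(default_factory=lambda: dict(_DEFAULT_BIAS))

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 0.05:
            raise ValueError("base_rate must be in (0, 0.05)")
        if min(self.sample_sd, self.resid_sd) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial depth per (sample, amplicon).

    At mean 7500 and dispersion 3.0 the 1st/99th percentiles are ~1100 and
    ~21000, reproducing the wide across-amplicon depth spread of the assay.
    An integer ``fixed`` depth overrides the distribution.
    """

    mean: float = 7500.0
    dispersion: float = 3.0
    fixed: Optional[int] = None

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.fixed is not None:
            return np.full(size, int(self.fixed), dtype=np.int64)
        p = self.dispersion / (self.dispersion + self.mean)
        d = rng.negative_binomial(self.dispersion, p, size=size)
        return np.maximum(d, 1)


@dataclass(frozen=True)
class InjectedVariant:
    """A true variant spiked into the simulation."""

    amplicon: str
    offset: int
    ref: str
    alt: str
    maf: float
    samples: Optional[tuple[str, ...]] = None  # None = all samples

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 1:
            raise ValueError("maf must be in (0, 1]")

    def carried_by(self, sample: str) -> bool:
        return self.samples is None or sample in self.samples


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def synthetic_panel(
    n_amplicons: int = 43,
    seed: int = 0,
    length_range: tuple[int, int] = (100, 175),
    primer_len: int = 20,
    spacer: int = 300,
) -> tuple[AmpliconPanel, dict[str, str]]:
    """Generate a random amplicon panel planted in a synthetic reference.

    Amplicons are random sequences of lengths drawn uniformly from
    ``length_range``; roughly half are planted in reverse-complement
    orientation so minus-strand coordinate handling is exercised.  Returns
    the anchored panel and the {chrom: sequence} reference it was planted in.
    """
    rng = np.random.default_rng(seed)
    amplicons, fragments = [], []
    pos = 0
    genome_parts = []
    for i in range(n_amplicons):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        while True:
            seq = _random_sequence(rng, length)
            if seq != revcomp(seq) and all(
                seq not in f and revcomp(seq) not in f for f in fragments
            ):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        planted = seq if strand == "+" else revcomp(seq)
        gap = _random_sequence(rng, spacer)
        genome_parts += [gap, planted]
        fragments.append(planted)
        amplicons.append(
            Amplicon(
                name=f"AMP{i + 1:02d}_{_GENES[i % len(_GENES)]}",
                sequence=seq,
                pool=i % 6 + 1,
                fwd_primer_len=primer_len,
                rev_primer_len=primer_len,
            )
        )
    genome_parts.append(_random_sequence(rng, spacer))
    reference = {"chrS": "".join(genome_parts)}
    panel = anchor_amplicons(AmpliconPanel(amplicons, version="synthetic"), reference)
    return panel, reference


def synthetic_catalogue(
    panel: AmpliconPanel,
    n_per_amplicon: int = 2,
    n_snps: int = 5,
    seed: int = 0,
) -> tuple[Catalogue, list[InjectedVariant]]:
    """Random known-mutation catalogue over a panel, plus matching variant specs.

    Picks ``n_per_amplicon`` hotspot positions per amplicon (outside primer
    regions), assigns each a substitution, and flags ``n_snps`` additional
    entries as germline SNPs.  Returns the catalogue together with ready-made
    :class:`InjectedVariant` templates (maf 0.01; adjust per use) for the
    somatic entries.
    """
    rng = np.random.default_rng(seed)
    entries, variants = [], []
    vid = 0
    for amp in panel:
        offsets = rng.choice(
            np.arange(amp.fwd_primer_len + 1, amp.length - amp.rev_primer_len + 1),
            size=n_per_amplicon,
            replace=False,
        )
        gene = amp.name.split("_", 1)[1] if "_" in amp.name else amp.name
        for off in sorted(int(o) for o in offsets):
            ref_local = amp.base_at(off)
            alt_local = str(rng.choice([b for b in _BASES if b != ref_local]))
            chrom, pos = amplicon_to_genome(panel, amp.name, off)
            vid += 1
            entries.append(
                CatalogueEntry(
                    chrom=chrom,
                    pos=pos,
                    ref=plus_strand_allele(amp, ref_local),
                    alt=plus_strand_allele(amp, alt_local),
                    gene=gene,
                    variant_id=f"COSV{vid:06d}",
                    is_snp=False,
                )
            )
            variants.append(
                InjectedVariant(amp.name, off, ref_local, alt_local, maf=0.01)
            )
    # SNP-flagged entries at further positions
    amp_cycle = list(panel)
    taken = {(v.amplicon, v.offset) for v in variants}
    i = 0
    while n_snps > 0 and i < 10 * len(amp_cycle):
        amp = amp_cycle[i % len(amp_cycle)]
        off = int(
            rng.integers(amp.fwd_primer_len + 1, amp.length - amp.rev_primer_len + 1)
        )
        i += 1
        if (amp.name, off) in taken:
            continue
        taken.add((amp.name, off))
        ref_local = amp.base_at(off)
        alt_local = str(rng.choice([b for b in _BASES if b != ref_local]))
        chrom, pos = amplicon_to_genome(panel, amp.name, off)
        vid += 1
        entries.append(
            CatalogueEntry(
                chrom=chrom,
                pos=pos,
                ref=plus_strand_allele(amp, ref_local),
                alt=plus_strand_allele(amp, alt_local),
                gene=amp.name.split("_", 1)[-1],
                variant_id=f"COSV{vid:06d}",
                is_snp=True,
            )
        )
        n_snps -= 1
    return Catalogue(entries), variants


def _bias_alt(rng: np.random.Generator, ref: str, bias: dict) -> str:
    alts = [b for b in _BASES if b != ref]
    w = np.array([bias.get(ref, {}).get(b, 1.0) for b in alts], float)
    return str(rng.choice(alts, p=w / w.sum()))


def simulate_pileup_counts(
    panel: AmpliconPanel,
    samples: Sequence[str],
    error: Optional[ErrorModel] = None,
    variants: Sequence[InjectedVariant] = (),
    depth_model: Union[DepthModel, int, None] = None,
    seed: int = 0,
    mask_primers: bool = True,
) -> pd.DataFrame:
    """Simulate a per-position count table for a set of samples.

    Per (sample, amplicon, offset) the error count is binomial with

        p = inv-logit(logit(base_rate) + beta1_true * offset
                      + sample_offset + N(0, resid_sd^2))

    assigned to one substitution-biased alt allele per site (sequencing error
    at a site is dominated by one substitution mode).  Injected variants add
    independent binomial counts at their mutant allele fraction on top of the
    noise.  Depth is negative-binomial per (sample, amplicon) and shared by
    that amplicon's offsets, as in real amplicon data where reads span the
    whole insert.
    """
    error = error or ErrorModel()
    if depth_model is None:
        depth_model = DepthModel()
    elif isinstance(depth_model, (int, np.integer)):
        depth_model = DepthModel(fixed=int(depth_model))
    rng = np.random.default_rng(seed)
    samples = [str(s) for s in samples]
    var_by_site: dict[tuple[str, int], list[InjectedVariant]] = {}
    for v in variants:
        amp = panel[v.amplicon]
        if not 1 <= v.offset <= amp.length:
            raise ValueError(f"variant offset {v.offset} outside amplicon {v.amplicon!r}")
        if amp.base_at(v.offset) != v.ref:
            raise ValueError(
                f"variant ref {v.ref!r} does not match amplicon "
                f"{v.amplicon!r} base at offset {v.offset}"
            )
        var_by_site.setdefault((v.amplicon, v.offset), []).append(v)

    sample_offsets = dict(
        zip(samples, rng.normal(0.0, error.sample_sd, size=len(samples)))
    )
    eta0 = float(logit(error.base_rate))
    rows: list[tuple] = []
    for amp in panel:
        offs = np.array(list(amp.insert_offsets(mask_primers)), dtype=np.int64)
        refs = np.array([amp.base_at(int(o)) for o in offs])
        err_alt = np.array(
            [_bias_alt(rng, r, error.substitution_bias) for r in refs]
        )
        chrom_pos = [amplicon_to_genome(panel, amp.name, int(o)) for o in offs]
        ref_plus = np.array([plus_strand_allele(amp, r) for r in refs])
        alt_plus = np.array([plus_strand_allele(amp, a) for a in err_alt])
        for s in samples:
            depth = int(depth_model.draw(rng, 1)[0])
            eta = (
                eta0
                + error.beta1_true * offs
                + sample_offsets[s]
                + rng.normal(0.0, error.resid_sd, size=offs.size)
            )
            err_counts = rng.binomial(depth, expit(eta))
            extra: dict[int, dict[str, int]] = {}
            for (amp_name, off), site_vars in var_by_site.items():
                if amp_name != amp.name:
                    continue
                for v in site_vars:
                    if not v.carried_by(s):
                        continue
                    n = int(rng.binomial(depth, v.maf))
                    if n:
                        extra.setdefault(off, {})[v.alt] = (
                            extra.get(off, {}).get(v.alt, 0) + n
                        )
            for i, off in enumerate(offs):
                off = int(off)
                site_alleles: dict[str, int] = {}
                if err_counts[i]:
                    site_alleles[str(err_alt[i])] = int(err_counts[i])
                for alt_local, n in extra.get(off, {}).items():
                    site_alleles[alt_local] = site_alleles.get(alt_local, 0) + n
                for alt_local in sorted(site_alleles):
                    rows.append(
                        (
                            s,
                            amp.name,
                            off,
                            chrom_pos[i][0],
                            chrom_pos[i][1],
                            str(ref_plus[i]),
                            plus_strand_allele(amp, alt_local)
                            if alt_local != str(err_alt[i])
                            else str(alt_plus[i]),
                            site_alleles[alt_local],
                            depth,
                        )
                    )
    return pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)


def simulate_dilution_series(
    panel: AmpliconPanel,
    genotype_a_variants: Sequence[InjectedVariant],
    genotype_b_variants: Sequence[InjectedVariant],
    fractions: Sequence[float],
    depth: Union[DepthModel, int, None] = None,
    error: Optional[ErrorModel] = None,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Simulate mixing two genotypes at the given genomic-DNA fractions.

    Genotype variants are monoallelic, so a mix containing fraction ``f`` of
    genotype B carries B's variants at mutant allele fraction ``f / 2`` and
    A's at ``(1 - f) / 2`` (a 1.25% genomic mix corresponds to ~0.6% MAF).
    Returns one count table per fraction; the sample id encodes the mix.
    """
    keys_a = {(v.amplicon, v.offset) for v in genotype_a_variants}
    keys_b = {(v.amplicon, v.offset) for v in genotype_b_variants}
    if keys_a & keys_b:
        raise ValueError("genotype variant sets must be disjoint")
    from dataclasses import replace as dc_replace

    tables = []
    for i, f in enumerate(fractions):
        if not 0 <= f <= 1:
            raise ValueError("fractions must be within [0, 1]")
        mix: list[InjectedVariant] = []
        if 1 - f > 0:
            mix += [dc_replace(v, maf=(1 - f) / 2) for v in genotype_a_variants]
        if f > 0:
            mix += [dc_replace(v, maf=f / 2) for v in genotype_b_variants]
        sample = f"mix_{f:g}"
        tables.append(
            simulate_pileup_counts(
                panel,
                [sample],
                error=error,
                variants=mix,
                depth_model=depth,
                seed=seed * 1009 + i,
            )
        )
    return tables


def simulate_fastq(
    panel: AmpliconPanel,
    reads_per_amplicon: Union[int, dict[str, int]],
    out_path: Union[str, Path],
    seed: int = 0,
    read_len: int = 150,
    mean_q: float = 35.0,
    sd_q: float = 3.0,
    error_rate: Optional[float] = None,
    forced_alt: Sequence[tuple[str, int, str, int]] = (),
    low_q_tail: int = 0,
    sample_id: str = "S1",
) -> Path:
    """Write simulated single-end reads (phred33 FASTQ) for a panel.

    Reads copy the amplicon sequence (truncated to ``read_len``), alternate
    strands, and carry per-base substitution errors with probability
    ``10**(-q/10)`` for the base's drawn quality (or a fixed ``error_rate``).
    ``forced_alt`` entries (amplicon, offset, alt_base, n_reads) plant true
    variants; ``low_q_tail`` appends that many q=2 bases to exercise
    trimming.  Deterministic: the same seed yields identical bytes.
    """
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    forced: dict[str, list[tuple[int, str, int]]] = {}
    for amp_name, off, alt, n in forced_alt:
        forced.setdefault(amp_name, []).append((off, alt, n))
    with open(out_path, "w") as fh:
        for amp in panel:
            n_reads = (
                reads_per_amplicon[amp.name]
                if isinstance(reads_per_amplicon, dict)
                else int(reads_per_amplicon)
            )
            plan = forced.get(amp.name, [])
            forced_assign: list[Optional[tuple[int, str]]] = []
            for off, alt, n in plan:
                forced_assign += [(off, alt)] * n
            forced_assign += [None] * (n_reads - len(forced_assign))
            for j in range(n_reads):
                template = list(amp.sequence[:read_len])
                quals = np.clip(
                    np.rint(rng.normal(mean_q, sd_q, size=len(template))), 2, 40
                ).astype(int)
                p_err = (
                    np.full(len(template), error_rate)
                    if error_rate is not None
                    else 10.0 ** (-quals / 10.0)
                )
                flips = np.nonzero(rng.random(len(template)) < p_err)[0]
                for k in flips:
                    template[k] = str(
                        rng.choice([b for b in _BASES if b != template[k]])
                    )
                spec = forced_assign[j]
                if spec is not None:
                    off, alt = spec
                    if off <= len(template):
                        template[off - 1] = alt
                bases = "".join(template)
                q = list(quals)
                if low_q_tail:
                    bases += _random_sequence(rng, low_q_tail)
                    q += [2] * low_q_tail
                strand = "+" if j % 2 == 0 else "-"
                if strand == "-":
                    bases = revcomp(bases)
                    q = q[::-1]
                fh.write(
                    f"@{sample_id}:{amp.name}:{j}\n{bases}\n+\n"
                    + "".join(chr(v + 33) for v in q)
                    + "\n"
                )
    return out_path


def simulate_serial_cohort(
    panel: AmpliconPanel,
    candidate_variants: Sequence[InjectedVariant],
    n_patients: int = 5,
    samples_per_patient: int = 2,
    n_recurrent: int = 2,
    n_sporadic: int = 1,
    recurrent_maf_median: float = 0.0225,
    sporadic_maf_median: float = 0.010,
    maf_sigma: float = 0.6,
    min_maf: float = 0.005,
    error: Optional[ErrorModel] = None,
    depth: Union[DepthModel, int, None] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate serial cfDNA samples for a cohort of patients.

    Each patient carries ``n_recurrent`` persistent mutations (present at
    every time point, MAFs log-normal around ``recurrent_maf_median``) and
    ``n_sporadic`` transient ones (one random time point each, lower MAFs);
    all MAFs are truncated to at least ``min_maf``, the assay's reporting
    floor.  Returns (count table, sample sheet, truth table); the truth table
    records every injected mutation for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    statuses = ("regressive", "stable", "progressive")

    def draw_maf(median: float) -> float:
        for _ in range(100):
            m = float(np.exp(rng.normal(np.log(median), maf_sigma)))
            if min_maf <= m <= 0.5:
                return m
        return min_maf

    all_samples: list[str] = []
    sheet_rows, truth_rows = [], []
    variants: list[InjectedVariant] = []
    candidates = list(candidate_variants)
    per_patient = n_recurrent + n_sporadic
    if per_patient * n_patients > len(candidates):
        raise ValueError("not enough candidate variants for the requested cohort")
    order = rng.permutation(len(candidates))
    from dataclasses import replace as dc_replace

    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        sample_ids = [f"{patient}_T{t + 1}" for t in range(samples_per_patient)]
        all_samples += sample_ids
        for t, sid in enumerate(sample_ids):
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "time_index": t + 1,
                    "clinical_status": statuses[int(rng.integers(len(statuses)))],
                    "replicate_of": "",
                }
            )
        chosen = [candidates[i] for i in order[p * per_patient : (p + 1) * per_patient]]
        for k, cand in enumerate(chosen):
            is_recurrent = k < n_recurrent
            maf = draw_maf(recurrent_maf_median if is_recurrent else sporadic_maf_median)
            carriers = (
                tuple(sample_ids)
                if is_recurrent
                else (sample_ids[int(rng.integers(samples_per_patient))],)
            )
            variants.append(dc_replace(cand, maf=maf, samples=carriers))
            chrom, pos = amplicon_to_genome(panel, cand.amplicon, cand.offset)
            amp = panel[cand.amplicon]
            for sid in carriers:
                truth_rows.append(
                    {
                        "patient": patient,
                        "sample": sid,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": plus_strand_allele(amp, cand.ref),
                        "alt": plus_strand_allele(amp, cand.alt),
                        "amplicon": cand.amplicon,
                        "offset": cand.offset,
                        "true_maf": maf,
                        "recurrence": "recurrent" if is_recurrent else "sporadic",
                    }
                )
    counts = simulate_pileup_counts(
        panel,
        all_samples,
        error=error,
        variants=variants,
        depth_model=depth,
        seed=seed + 1,
    )
    return counts, pd.DataFrame(sheet_rows), pd.DataFrame(truth_rows)
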