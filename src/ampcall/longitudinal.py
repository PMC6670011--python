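"""Longitudinal tracking of mutations across serial samples.

Serial plasma samples of one patient are compared by mutation key
(chrom, pos, ref, alt): a mutation seen in at least two samples of a patient
is *recurrent*, one seen in exactly one sample is *sporadic*.  Cohort-level
summaries (mutations per sample, AF distribution, per-gene counts, clinical
status breakdown) and replicate concordance mirror the standard read-outs of
a liquid-biopsy monitoring study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SerialSampleSet",
    "load_sample_sheet",
    "classify_recurrence",
    "summarize_cohort",
    "replicate_concordance",
    "trajectory_table",
]

CLINICAL_STATUSES = ("regressive", "stable", "progressive", "unknown")

MUTATION_KEY = ["chrom", "pos", "ref", "allele"]


@dataclass
class SerialSampleSet:
    """Time-ordered samples of one patient."""

    patient_id: str
    samples: list[tuple[str, float, str]]  # (sample_id, time, clinical status)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"patient {self.patient_id!r}: no samples")
        times = [t for _, t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"patient {self.patient_id!r}: times not strictly increasing")
        for _, _, status in self.samples:
            if status not in CLINICAL_STATUSES:
                raise ValueError(f"unknown clinical status {status!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]


def load_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    """Read the sample sheet TSV.

    Expected header: ``sample_id  patient_id  time_index  clinical_status``
    plus an optional ``replicate_of`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["time_index"] = df["time_index"].astype(float)
    if "clinical_status" not in df.columns:
        df["clinical_status"] = "unknown"
    if "replicate_of" not in df.columns:
        df["replicate_of"] = ""
    df["replicate_of"] = df["replicate_of"].fillna("")
    return df


def sample_sets(sheet: pd.DataFrame) -> dict[str, SerialSampleSet]:
    """Group a sample sheet into per-patient serial sample sets (replicates excluded)."""
    out = {}
    primary = sheet.loc[sheet["replicate_of"] == ""]
    for patient, grp in primary.groupby("patient_id"):
        grp = grp.sort_values("time_index")
        out[str(patient)] = SerialSampleSet(
            str(patient),
            [
                (str(r.sample_id), float(r.time_index), str(r.clinical_status))
                for r in grp.itertuples()
            ],
        )
    return out


def _annotated(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.loc[calls["status"] == "annotated"]


def classify_recurrence(
    patient: SerialSampleSet, calls: pd.DataFrame
) -> Optional[dict[tuple, str]]:
    """Classify each of a patient's mutations as recurrent or sporadic.

    A mutation key present in >= 2 of the patient's serial samples (not
    necessarily consecutive) is recurrent; present in exactly one, sporadic.
    Returns ``None`` for single-sample patients, for whom the distinction is
    undefined.
    """
    if len(patient.samples) < 2:
        return None
    ann = _annotated(calls)
    ann = ann.loc[ann["sample"].isin(patient.sample_ids)]
    if ann.empty:
        return {}
    per_key = ann.drop_duplicates(subset=MUTATION_KEY + ["sample"]).groupby(
        MUTATION_KEY
    )["sample"].nunique()
    return {
        key: ("recurrent" if n >= 2 else "sporadic") for key, n in per_key.items()
    }


@dataclass
class CohortSummary:
    """Cohort-level descriptive statistics of annotated mutations."""

    n_samples: int
    n_mutations: int
    mean_mutations_per_sample: float
    af_median: float
    af_min: float
    af_max: float
    per_gene: pd.Series = field(repr=False)
    per_status: pd.Series = field(repr=False)
    recurrent_vs_sporadic_p: Optional[float] = None
    recurrent_af_median: Optional[float] = None
    sporadic_af_median: Optional[float] = None


def summarize_cohort(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
    alternative: str = "two-sided",
) -> CohortSummary:
    """Summarize annotated mutations across the cohort.

    Reports the mean number of annotated mutations per sample (samples with
    none count as zero), the AF median/min/max, per-gene and per-clinical-
    status counts, and a two-sample Wilcoxon rank-sum comparison of recurrent
    vs sporadic mutation AFs (pooled over patients with >= 2 samples).
    Statistics are invariant to sample ordering.
    """
    ann = _annotated(calls)
    samples = sheet["sample_id"].astype(str)
    per_sample = (
        ann.groupby("sample").size().reindex(samples, fill_value=0).astype(float)
    )
    af = ann["af"].to_numpy(float)
    status_of = sheet.set_index("sample_id")["clinical_status"]
    per_status = (
        ann["sample"].map(status_of).value_counts().sort_index()
        if len(ann)
        else pd.Series(dtype=int)
    )
    rec_af, spo_af = [], []
    for patient, sset in sample_sets(sheet).items():
        classes = classify_recurrence(sset, calls)
        if not classes:
            continue
        sub = ann.loc[ann["sample"].isin(sset.sample_ids)]
        for key, grp in sub.groupby(MUTATION_KEY):
            label = classes.get(key)
            target = rec_af if label == "recurrent" else spo_af
            target.extend(grp["af"].tolist())
    p = None
    if len(rec_af) >= 2 and len(spo_af) >= 2:
        p = float(
            stats.mannwhitneyu(rec_af, spo_af, alternative=alternative).pvalue
        )
    return CohortSummary(
        n_samples=len(samples),
        n_mutations=int(len(ann)),
        mean_mutations_per_sample=float(per_sample.mean()) if len(per_sample) else 0.0,
        af_median=float(np.median(af)) if af.size else float("nan"),
        af_min=float(af.min()) if af.size else float("nan"),
        af_max=float(af.max()) if af.size else float("nan"),
        per_gene=ann.groupby("gene").size().sort_values(ascending=False)
        if len(ann)
        else pd.Series(dtype=int),
        per_status=per_status,
        recurrent_vs_sporadic_p=p,
        recurrent_af_median=float(np.median(rec_af)) if rec_af else None,
        sporadic_af_median=float(np.median(spo_af)) if spo_af else None,
    )


@dataclass
class ConcordanceResult:
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    n_shared: int
    n_unique_1: int
    n_unique_2: int


def replicate_concordance(
    calls_1: pd.DataFrame,
    calls_2: pd.DataFrame,
    mode: str = "intersection",
) -> ConcordanceResult:
    """AF concordance between two replicates of the same sample.

    ``mode='intersection'`` (default) correlates AFs over mutations detected
    in both replicates, matching how replicate scatter plots show only
    detected mutations; ``mode='union'`` correlates over the union of keys
    with AF 0 substituted for absent calls.  Correlations are unavailable
    (``None``) when fewer than 3 mutation keys enter the comparison.
    """
    af1 = _annotated(calls_1).groupby(MUTATION_KEY)["af"].max()
    af2 = _annotated(calls_2).groupby(MUTATION_KEY)["af"].max()
    shared = af1.index.intersection(af2.index)
    n_unique_1 = len(af1.index.difference(af2.index))
    n_unique_2 = len(af2.index.difference(af1.index))
    if mode == "union":
        keys = af1.index.union(af2.index)
        x = af1.reindex(keys, fill_value=0.0).to_numpy(float)
        y = af2.reindex(keys, fill_value=0.0).to_numpy(float)
    elif mode == "intersection":
        x = af1.reindex(shared).to_numpy(float)
        y = af2.reindex(shared).to_numpy(float)
    else:
        raise ValueError(f"unknown concordance mode {mode!r}")
    pearson = spearman = None
    if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    return ConcordanceResult(
        pearson_r=pearson,
        spearman_rho=spearman,
        n_shared=len(shared),
        n_unique_1=n_unique_1,
        n_unique_2=n_unique_2,
    )


def trajectory_table(calls: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Long-format table of mutation AFs over time, one row per
    (patient, mutation, time point), suitable for trajectory plotting."""
    ann = _annotated(calls)
    meta = sheet.set_index("sample_id")[["patient_id", "time_index", "clinical_status"]]
    rows = []
    for patient, sset in sample_sets(sheet).items():
        classes = classify_recurrence(sset, calls) or {}
        sub = ann.loc[ann["sample"].isin(sset.sample_ids)]
        for r in sub.itertuples():
            key = (r.chrom, r.pos, r.ref, r.allele)
            m = meta.loc[r.sample]
            rows.append(
                {
                    "patient": patient,
                    "mutation": f"{r.chrom}:{r.pos}{r.ref}>{r.allele}",
                    "gene": getattr(r, "gene", ""),
                    "time_index": float(m["time_index"]),
                    "af": r.af,
                    "clinical_status": m["clinical_status"],
                    "recurrence": classes.get(key, "unclassified"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient",
            "mutation",
            "gene",
            "time_index",
            "af",
            "clinical_status",
            "recurrence",
        ],
    ).sort_values(["patient", "mutation", "time_index"], ignore_index=True)
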