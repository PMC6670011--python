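"""In-silico validation experiments for the calling workflow.

These functions reproduce the standard characterization experiments of a
low-frequency amplicon caller entirely in simulation: a two-genotype
dilution series to measure the detection limit, a randomized allele-
frequency sweep to verify the reporting floor, pure-noise runs for the
false-positive rate, parameter-recovery checks for the noise model, and
replicate concordance.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .longitudinal import replicate_concordance
from .noise import fit_and_call, fit_noise_model
from .panel import amplicon_to_genome, plus_strand_allele
from .pileup import observations_from_table
from .pipeline import PipelineParams, call_pipeline_from_counts
from .simulate import (
    DepthModel,
    InjectedVariant,
    simulate_dilution_series,
    simulate_pileup_counts,
    synthetic_catalogue,
    synthetic_panel,
)

__all__ = [
    "dilution_detection",
    "af_floor_experiment",
    "pure_noise_call_rate",
    "beta1_recovery",
    "replicate_concordance_experiment",
]

DEFAULT_FRACTIONS = (0.20, 0.10, 0.05, 0.025, 0.0125)


@dataclass
class DilutionResult:
    """Detection shares per mix fraction plus the inferred limits."""

    table: pd.DataFrame  # fraction, maf, n_seeds, n_detected, share
    min_detectable_maf: float  # smallest MAF with share >= min_share
    min_detectable_fraction: float

    def __repr__(self) -> str:  # compact, for interactive use
        return (
            f"DilutionResult(min maf {self.min_detectable_maf:.4%}, "
            f"min mix {self.min_detectable_fraction:.4%})"
        )


def _panel_and_catalogue(n_amplicons: int, seed: int):
    panel, _ = synthetic_panel(n_amplicons=n_amplicons, seed=seed)
    catalogue, variants = synthetic_catalogue(panel, n_per_amplicon=2, seed=seed + 1)
    return panel, catalogue, variants


def dilution_detection(
    fractions=DEFAULT_FRACTIONS,
    n_seeds: int = 20,
    depth_mean: float = 7500.0,
    n_amplicons: int = 43,
    n_variants_per_genotype: int = 3,
    n_background: int = 25,
    min_share: float = 0.95,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> DilutionResult:
    """Measure the dilution-series detection limit of the full caller.

    Two synthetic genotypes with disjoint monoallelic variant sets (one
    variant per amplicon, 3 per genotype by default - about what a CRC
    hotspot panel covers in a typical cell line) are mixed at the given
    genomic-DNA fractions (minor-genotype MAF = fraction / 2).  The mixes of
    one seed are processed jointly with ``n_background`` noise-only samples,
    emulating a MiSeq run of ~30 samples in which the dilution series is a
    small subset; with the mixes alone, the spiked variants would dominate
    every sample of the run and inflate their own amplicons' residual SD.  A
    fraction counts as detected in a seed when *every* minor-genotype
    variant is called and annotated in that mix's sample.  The detection
    limit is the smallest MAF (and mix fraction) whose detection share over
    seeds reaches ``min_share``.
    """
    params = params or PipelineParams()
    panel, catalogue, candidates = _panel_and_catalogue(n_amplicons, seed)
    # stride 2: synthetic_catalogue emits two candidates per amplicon, take
    # one so each genotype variant sits on its own amplicon
    geno_a = [replace(candidates[2 * i], maf=0.5) for i in range(n_variants_per_genotype)]
    geno_b = [
        replace(candidates[2 * i], maf=0.5)
        for i in range(n_variants_per_genotype, 2 * n_variants_per_genotype)
    ]
    b_keys = {
        _genomic_key(panel, v) for v in geno_b
    }
    detected = {f: 0 for f in fractions}
    for s in range(n_seeds):
        tables = simulate_dilution_series(
            panel,
            geno_a,
            geno_b,
            fractions,
            depth=DepthModel(mean=depth_mean),
            seed=seed + 7919 * (s + 1),
        )
        pieces = list(tables)
        if n_background:
            pieces.append(
                simulate_pileup_counts(
                    panel,
                    [f"BG{i:02d}" for i in range(n_background)],
                    depth_model=DepthModel(mean=depth_mean),
                    seed=seed + 104659 * (s + 1),
                )
            )
        counts = pd.concat(pieces, ignore_index=True)
        result = call_pipeline_from_counts(counts, panel, catalogue, params=params)
        ann = result.calls.loc[result.calls["status"] == "annotated"]
        for f, table in zip(fractions, tables):
            sample = str(table["sample"].iloc[0])
            found = {
                (r.chrom, r.pos, r.ref, r.allele)
                for r in ann.loc[ann["sample"] == sample].itertuples()
            }
            if b_keys <= found:
                detected[f] += 1
    rows = [
        {
            "fraction": f,
            "maf": f / 2,
            "n_seeds": n_seeds,
            "n_detected": detected[f],
            "share": detected[f] / n_seeds,
        }
        for f in sorted(fractions)
    ]
    table = pd.DataFrame(rows)
    ok = table.loc[table["share"] >= min_share]
    min_maf = float(ok["maf"].min()) if len(ok) else float("nan")
    min_frac = float(ok["fraction"].min()) if len(ok) else float("nan")
    return DilutionResult(table, min_maf, min_frac)


def _genomic_key(panel, v: InjectedVariant):
    chrom, pos = amplicon_to_genome(panel, v.amplicon, v.offset)
    amp = panel[v.amplicon]
    return (chrom, pos, plus_strand_allele(amp, v.ref), plus_strand_allele(amp, v.alt))


def af_floor_experiment(
    n_samples: int = 50,
    n_amplicons: int = 43,
    af_range: tuple[float, float] = (0.0001, 0.1),
    seed: int = 0,
    params: PipelineParams | None = None,
) -> tuple[float, pd.DataFrame]:
    """Sweep injected MAFs across decades and report the smallest reported AF.

    Each sample carries one catalogue variant with a MAF from a log-spaced
    grid over ``af_range``; after the full caller runs, the minimum AF over
    all called/annotated mutations is returned (the assay's hard reporting
    floor is 0.5%).
    """
    params = params or PipelineParams()
    panel, catalogue, candidates = _panel_and_catalogue(n_amplicons, seed)
    mafs = np.geomspace(af_range[0], af_range[1], n_samples)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    variants = [
        replace(candidates[i % len(candidates)], maf=float(mafs[i]), samples=(samples[i],))
        for i in range(n_samples)
    ]
    counts = simulate_pileup_counts(
        panel, samples, variants=variants, depth_model=DepthModel(), seed=seed + 13
    )
    result = call_pipeline_from_counts(counts, panel, catalogue, params=params)
    reported = result.calls.loc[result.calls["status"].isin(("called", "annotated"))]
    min_af = float(reported["af"].min()) if len(reported) else float("nan")
    return min_af, result.calls


def pure_noise_call_rate(
    n_seeds: int = 100,
    n_amplicons: int = 6,
    n_samples: int = 5,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> np.ndarray:
    """Pre-catalogue call rate on pure noise (no injected variants), per seed.

    Under the median + 3 SD residual rule on approximately normal residuals
    the expected rate is ~0.13%; robust-scale effects can raise it somewhat
    but it should stay well below 1%.
    """
    params = params or PipelineParams()
    panel, _ = synthetic_panel(n_amplicons=n_amplicons, seed=seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    rates = np.empty(n_seeds)
    for s in range(n_seeds):
        counts = simulate_pileup_counts(
            panel, samples, depth_model=DepthModel(), seed=seed + 104729 * (s + 1)
        )
        obs = observations_from_table(counts, min_depth=params.min_depth)
        _, calls = fit_and_call(
            obs, sd_threshold=params.sd_threshold, min_af=params.min_af
        )
        rates[s] = (calls["status"] == "called").mean() if len(calls) else 0.0
    return rates


def beta1_recovery(
    n_seeds: int = 100,
    n_positions: int = 150,
    n_samples: int = 10,
    beta0: float = -6.9,
    beta1: float = 0.005,
    sample_sd: float = 0.2,
    resid_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the noise model to data generated exactly from its own assumptions.

    Observations are logit allele frequencies lying on the generating plane
    plus Gaussian noise; for each seed the fitted position slope and sample
    offsets are compared to their generating values in units of the fit's
    standard errors.  Returns one row per seed with coverage indicators.
    """
    rows = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 31 * (s + 1))
        offsets = np.tile(np.arange(1, n_positions + 1), n_samples)
        sample_ids = np.repeat([f"S{i:02d}" for i in range(n_samples)], n_positions)
        effects = rng.normal(0, sample_sd, n_samples)
        effects -= effects[0]  # reference coding: first sample is baseline
        eff = np.repeat(effects, n_positions)
        y = beta0 + beta1 * offsets + eff + rng.normal(0, resid_sd, offsets.size)
        a = 1.0 / (1.0 + np.exp(-y))
        obs = pd.DataFrame(
            {"sample": sample_ids, "offset": offsets, "af": a, "amplicon": "A"}
        )
        fit = fit_noise_model(obs, amplicon="A")
        se1 = fit.bse["offset"]
        within_beta1 = abs(fit.beta1 - beta1) <= 2 * se1
        sample_hits = []
        for i in range(1, n_samples):
            name = f"sample[S{i:02d}]"
            se = fit.bse[name]
            sample_hits.append(abs(fit.beta_sample[f"S{i:02d}"] - effects[i]) <= 2 * se)
        rows.append(
            {
                "seed": s,
                "beta1_hat": fit.beta1,
                "beta1_se": se1,
                "beta1_within_2se": bool(within_beta1),
                "sample_within_2se_frac": float(np.mean(sample_hits)),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def replicate_concordance_experiment(
    n_variants: int = 10,
    depth: int = 7500,
    n_amplicons: int = 12,
    seed: int = 0,
    params: PipelineParams | None = None,
):
    """Two independent simulated replicates of one sample sharing its true
    mutations (all >= 0.5% AF); returns the concordance of reported AFs."""
    params = params or PipelineParams()
    panel, catalogue, candidates = _panel_and_catalogue(n_amplicons, seed)
    rng = np.random.default_rng(seed + 5)
    mafs = np.geomspace(0.006, 0.20, n_variants)
    variants = [
        replace(candidates[i], maf=float(mafs[i])) for i in rng.permutation(n_variants)
    ]
    results = []
    for rep in (1, 2):
        counts = simulate_pileup_counts(
            panel,
            [f"R{rep}"],
            variants=variants,
            depth_model=depth,
            seed=seed + 100 + rep,
        )
        results.append(
            call_pipeline_from_counts(counts, panel, catalogue, params=params).calls
        )
    return replicate_concordance(results[0], results[1], mode="intersection")
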