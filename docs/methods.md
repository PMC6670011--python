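# Methods

`ampcall` implements an end-to-end workflow for detecting low-frequency
somatic mutations in deep multiplex amplicon sequencing of cell-free DNA
(cfDNA), of the kind produced by a custom ~43-amplicon hotspot panel
sequenced 150 bp single-end on a MiSeq. This note documents the model, the
parameters that matter, the synthetic-data generator, and the numerical and
design choices.

## The noise model

Deep amplicon sequencing of cfDNA observes thousands of non-reference
alleles per sample, nearly all of which are PCR or sequencing errors. The
caller separates true mutations from this error background with a
per-amplicon robust linear model on logit-transformed allele frequencies:

    log( a / (1 - a) ) = β₀ + β₁·X₁ + β₂·X₂ + ε

where `a` is the allele frequency of one observation (one non-reference
allele at one amplicon position in one sample), `X₁` is the 1-based position
of the variant on the amplicon (continuous), and `X₂` is the sample
(categorical, reference-coded; one offset per non-reference sample). The
model rests on three working assumptions: (a) the vast majority of
observations are errors, (b) PCR error rates vary smoothly with position
within an amplicon but are otherwise stable, and (c) sequencing error at a
given position is equally likely in every sample, up to a sample-level
offset.

The fit is a Huber M-estimate (tuning constant 1.345, 95% Gaussian
efficiency) computed by iteratively reweighted least squares, with the scale
re-estimated each iteration as MAD/0.6745 and convergence declared when the
coefficients change by less than 1e-8 (at most 50 iterations). The robust
loss is the crux: the rare true mutations are large positive outliers and
must not drag the fit. The implementation delegates the IRLS to
`statsmodels.RLM`; a Tukey bisquare loss is available behind the `loss`
option. Estimation uses the residual on the *unweighted* scale.

An observation is **called** a true mutation when both

1. its residual exceeds the median of its amplicon's residuals by at least
   `sd_threshold` (default 3) residual standard deviations, and
2. its allele frequency is at least `min_af` (default 0.005 = 0.5%), the
   clinical-relevance floor of the assay.

Called mutations are then matched against a COSMIC-style catalogue by exact
(chrom, pos, ref, alt); mutations absent from the catalogue or flagged as
germline SNPs are rejected. Every rejection carries a machine-readable
reason, and the stage audit telescopes exactly.

### Choices where the design was open

* **Sample term.** A scalar encoding of patient identity is meaningless, so
  `X₂` is a categorical factor with one coefficient per non-reference
  sample; assumption (c) is exactly a sample-level offset. A single-sample
  run drops the factor and fits intercept + slope only.
* **Residual scale.** "Standard deviations" is read literally: the
  unweighted sample SD of the per-amplicon residual vector (default). A
  MAD-based robust scale is available (`residual_scale="mad"`), as is a
  global pooled-residual mode (`pool_residuals=True`); per-amplicon is the
  default because the model is fit per amplicon. See *Known limitations*
  for the consequences of the SD default.
* **Observation unit.** Each distinct alt allele at a position in a sample
  is a separate observation; zero counts are never observations.
* **Degenerate inputs.** `a = 1` is clamped to `(depth - 0.5)/depth` so the
  logit stays finite; amplicons whose design matrix is underdetermined or
  rank-deficient are flagged unfittable and their observations rejected
  with reason `insufficient-data`; a zero-variance residual vector gets an
  SD floor of 1e-8.
* **Depth floor.** Pileup columns with fewer than 100 qualifying reads emit
  no observations — their logit allele fractions are dominated by counting
  noise. Configurable (`min_depth`).
* **Primer masking.** The first/last primer-length bases of each amplicon
  are excluded from calling by default: primer-derived bases are synthetic
  and cannot carry template variants. Configurable (`mask_primers`).

## Read processing

Single-end phred33 reads are trimmed with trimmomatic-style rules in a fixed
order: leading bases with q < 15, trailing bases with q < 15, a 5'→3'
sliding window cut at the first 4-base window with mean quality < 15, then
removal of reads shorter than 70 bases. After the window cut the trailing
rule is re-applied so that trimming is idempotent (a single pass is not, in
the corner case where the base just before the cut window is below the
threshold).

Instead of a general-purpose genome aligner, reads are assigned directly to
panel amplicons: banded infix edit distance (via `edlib`) against every
amplicon on both strands, with assignment to the unique best hit iff the
best distance is ≤ ceil(0.10 × read length) *and* the second-best amplicon
is at least 2 edits worse. With a known target space of ~43 amplicons,
mapping ambiguity — the quantity a mapping-quality score measures — reduces
exactly to this best-vs-second-best margin. Users who prefer a conventional
bwa/samtools/bam-readcount stage can feed its per-position count table
directly to the caller (`counts` input); the count-table TSV is the
pipeline's exchange format either way.

Pileup counting honours the assay's base-quality rule: only bases with
phred ≥ 30 contribute to allele counts or depth; N bases are dropped.
Simple indels are carried as composite allele keys (`+SEQ`, `-N`)
left-anchored at the last aligned base and converted to padded REF/ALT only
at VCF export.

## Longitudinal analysis

Within a patient's time-ordered serial samples, a mutation key present in
≥ 2 samples (not necessarily consecutive) is *recurrent*; present in
exactly one, *sporadic*. The distinction is undefined for single-sample
patients. Cohort summaries report mutations per sample, the AF
distribution, per-gene counts, counts by clinical status and a two-sample
Wilcoxon rank-sum comparison of recurrent vs sporadic AFs. Replicate
concordance (Pearson and Spearman) is computed over mutations detected in
both replicates by default, mirroring how replicate scatter plots show only
detected mutations; a union-with-zeros mode exists.

## The synthetic-data generator

The generator realizes exactly the error structure the model assumes, so
the caller is testable end to end without controlled-access patient data:

* per (sample, amplicon, offset), error counts are binomial with
  `p = logit⁻¹( logit(base_rate) + beta1_true·offset + sample_offset + N(0, resid_sd²) )`,
  with defaults base_rate 0.001, beta1_true 0.005 per base, sample offsets
  N(0, 0.2²), resid_sd 0.3;
* each site's errors go to one substitution-biased alt allele
  (transition-weighted 4:1:1), reflecting the dominance of one error mode
  per site;
* depth is negative-binomial per (sample, amplicon) — shared across that
  amplicon's offsets, since reads span the whole insert — with mean 7500
  and dispersion 3.0, giving 1st/99th percentiles of roughly 1100/21000×.
  No NB dispersion at mean 7500 yields 1st/99th percentiles of 500 *and*
  21000 simultaneously; dispersion 3.0 matches the upper tail of the
  assay's observed across-amplicon spread and accepts a higher lower
  percentile;
* injected variants add independent binomial counts at their mutant allele
  fraction; dilution series model two genotypes with disjoint *monoallelic*
  variant sets, so a genomic mix fraction `f` yields minor-genotype MAF
  `f/2` (a 1.25% mix ≈ 0.625% MAF);
* serial cohorts draw per-patient persistent (recurrent) mutations at
  log-normal MAFs around 2.25% and transient (sporadic) ones around 1%,
  truncated at the 0.5% reporting floor;
* a FASTQ generator emits amplicon-copy reads with quality-dependent
  substitution errors for end-to-end tests through trimming and assignment.

All generators are pure functions of (parameters, seed): identical calls
produce byte-identical tables.

What the generator does *not* emulate: UMI families, primer-dimer
artifacts, polymerase-specific error spectra, strand bias, contamination,
copy-number effects and real COSMIC coordinates (the panel, reference and
catalogue are synthetic). Passing tests therefore demonstrate correctness
of the algorithmics and calibration under the model's own assumptions, not
performance on real cfDNA.

## In-silico validation experiments and problem sizes

`ampcall.experiments` packages the standard characterization experiments;
`scripts/acceptance.py` re-runs the headline ones. Problem sizes were
chosen to give stable estimates at interactive runtimes: the dilution
series uses a 43-amplicon panel, mixes 20/10/5/2.5/1.25%, 3 monoallelic
variants per genotype (about what a CRC hotspot panel covers in a typical
cell line, one variant per amplicon), depth mean 7500 and 20 seeds, with
the five mixes processed jointly with 25 noise-only background samples —
emulating a MiSeq run of ~30 samples in which a dilution series is a small
subset. The background matters: in a run consisting only of the five mixes,
every sample carries the spiked variants, and those outliers inflate their
own amplicons' residual SD (~0.46 → ~0.62) in a way no real run exhibits.
The AF-floor sweep injects one catalogue variant per sample at MAFs
log-spaced over 0.01%–10% across 50 samples; the false-positive experiment
runs 100 pure-noise seeds; parameter recovery fits 100 replicates of a
150-position × 10-sample amplicon generated from the model's own plane.

## Known limitations

* **Detection limit under the default error model.** With base_rate 0.001
  and depth ~7500, per-site error counts are small (λ ≈ 7–15), and their
  shot noise contributes ≈ 0.35 SD on the logit scale on top of resid_sd
  0.3. The per-amplicon residual SD is therefore ≈ 0.46, and the
  median + 3 SD threshold (≈ 1.4) coincides with the signal of a 0.625%-MAF
  variant over a ~0.13–0.2% error baseline (ln(1 + 0.00625/p) ≈ 1.4–2.0).
  In the packaged dilution experiment the 1.25% mix step is consequently
  detected in well under 95% of seeds, and the reliable detection limit
  lands one step higher (1.25% MAF / 2.5% mix). Reliable 0.6% detection
  would require a lower error baseline (e.g. post-Q30 error rates of a few
  1e-4) or greater depth; the MAD residual scale helps but does not close
  the gap. This is a property of the model-plus-threshold at these noise
  conditions, not of the implementation: at the same settings a 2% MAF
  variant is recovered in ≥ 99% of seeds and the pure-noise call rate stays
  well below 1%.
* The caller applies no multiple-testing correction (by design), no
  UMI-based error suppression, no local realignment, and does not detect
  copy-number changes or fusions.
* Recurrence classification ignores sampling depth differences between
  time points; a mutation near the AF floor may flip between recurrent and
  sporadic by detection chance alone.
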