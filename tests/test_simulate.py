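"""Synthetic-data generators: determinism, binomial oracles, dilution arithmetic."""

import numpy as np
import pytest

from ampcall.simulate import (
    DepthModel,
    ErrorModel,
    InjectedVariant,
    simulate_dilution_series,
    simulate_fastq,
    simulate_pileup_counts,
    simulate_serial_cohort,
)


def test_error_model_validation():
    with pytest.raises(ValueError):
        ErrorModel(base_rate=0.2)
    with pytest.raises(ValueError):
        InjectedVariant("A", 5, "A", "T", maf=0.0)


def test_same_seed_byte_identical_tables(small_panel):
    panel, _ = small_panel
    kw = dict(samples=["S1", "S2"], seed=42)
    t1 = simulate_pileup_counts(panel, **kw)
    t2 = simulate_pileup_counts(panel, **kw)
    assert t1.to_csv() == t2.to_csv()
    t3 = simulate_pileup_counts(panel, samples=["S1", "S2"], seed=43)
    assert t1.to_csv() != t3.to_csv()


def test_variant_offset_validation(small_panel):
    panel, _ = small_panel
    amp = next(iter(panel))
    bad = InjectedVariant(amp.name, amp.length + 10, "A", "T", maf=0.1)
    with pytest.raises(ValueError, match="outside"):
        simulate_pileup_counts(panel, ["S"], variants=[bad], seed=1)


def test_noise_rates_match_binomial_oracle(small_panel):
    """With all structure off, every alt fraction is within 3 binomial SDs
    of base_rate at depth 1e6."""
    panel, _ = small_panel
    quiet = ErrorModel(resid_sd=0.0, sample_sd=0.0, beta1_true=0.0, base_rate=0.001)
    t = simulate_pileup_counts(panel, ["S1"], error=quiet, depth_model=10**6, seed=5)
    frac = t["count"] / t["depth"]
    sd = np.sqrt(0.001 * 0.999 / 10**6)
    dev = np.abs(frac - 0.001)
    assert (dev <= 3 * sd).mean() >= 0.99  # ~99.7% expected under the oracle
    assert dev.max() <= 5 * sd


def test_depth_model_spread():
    rng = np.random.default_rng(0)
    d = DepthModel().draw(rng, 20000)
    q01, q50, q99 = np.quantile(d, [0.01, 0.5, 0.99])
    assert 800 <= q01 <= 1400
    assert 6000 <= q50 <= 7600
    assert 19000 <= q99 <= 23500


@pytest.fixture(scope="module")
def genotypes(small_panel):
    panel, _ = small_panel
    amps = list(panel)

    def var(amp, off):
        return InjectedVariant(amp.name, off, amp.base_at(off),
                               "A" if amp.base_at(off) != "A" else "G", maf=0.5)

    a = [var(amps[0], 30), var(amps[1], 40)]
    b = [var(amps[2], 30), var(amps[3], 40)]
    return a, b


class TestDilution:
    def test_mix_fraction_to_maf_arithmetic(self, small_panel, genotypes):
        """1.25% genomic mix of the minor genotype -> 0.625% MAF for its
        monoallelic variants (~0.6%, matching the two-cell-line design)."""
        panel, _ = small_panel
        a, b = genotypes
        quiet = ErrorModel(resid_sd=0.0, sample_sd=0.0, beta1_true=0.0)
        (t,) = simulate_dilution_series(panel, a, b, [0.0125], depth=10**6,
                                        error=quiet, seed=6)
        for v in b:
            row = t[(t.amplicon == v.amplicon) & (t.offset == v.offset)
                    & (t["count"] > 200)]
            af = float((row["count"] / row["depth"]).max())
            assert af == pytest.approx(0.00625, abs=3 * np.sqrt(0.00625 / 10**6))
        for v in a:
            row = t[(t.amplicon == v.amplicon) & (t.offset == v.offset)
                    & (t["count"] > 200)]
            af = float((row["count"] / row["depth"]).max())
            assert af == pytest.approx((1 - 0.0125) / 2, rel=0.01)

    def test_symmetric_mix(self, small_panel, genotypes):
        panel, _ = small_panel
        a, b = genotypes
        quiet = ErrorModel(resid_sd=0.0, sample_sd=0.0, beta1_true=0.0)
        (t,) = simulate_dilution_series(panel, a, b, [0.5], depth=10**6,
                                        error=quiet, seed=7)
        for v in a + b:
            row = t[(t.amplicon == v.amplicon) & (t.offset == v.offset)
                    & (t["count"] > 200)]
            assert float((row["count"] / row["depth"]).max()) == pytest.approx(
                0.25, rel=0.02)

    def test_zero_fraction_leaves_minor_genotype_absent(self, small_panel, genotypes):
        panel, _ = small_panel
        a, b = genotypes
        quiet = ErrorModel(resid_sd=0.0, sample_sd=0.0, beta1_true=0.0)
        (t,) = simulate_dilution_series(panel, a, b, [0.0], depth=10**5,
                                        error=quiet, seed=8)
        for v in b:
            row = t[(t.amplicon == v.amplicon) & (t.offset == v.offset)]
            mx = int(row["count"].max()) if len(row) else 0
            # nothing beyond noise-level counts (~100 +/- 10) at B positions
            assert mx <= 0.001 * 10**5 + 5 * np.sqrt(0.001 * 10**5)

    def test_overlapping_genotypes_rejected(self, small_panel, genotypes):
        panel, _ = small_panel
        a, _ = genotypes
        with pytest.raises(ValueError, match="disjoint"):
            simulate_dilution_series(panel, a, a, [0.1], seed=9)


class TestFastq:
    def test_deterministic_bytes(self, small_panel, tmp_path):
        panel, _ = small_panel
        p1 = simulate_fastq(panel, 5, tmp_path / "a.fastq", seed=3)
        p2 = simulate_fastq(panel, 5, tmp_path / "b.fastq", seed=3)
        assert p1.read_bytes() == p2.read_bytes()

    def test_forced_alt_reaches_target_af(self, small_panel, tmp_path):
        """1000 reads with 10 forced alt at one offset -> AF 1% at that
        position after trimming, assignment and pileup."""
        from ampcall.panel import AmpliconPanel
        from ampcall.pileup import build_pileup, compute_af
        from ampcall.reads import assign_read, read_fastq, trim_read

        panel, _ = small_panel
        amp = list(panel)[1]
        sub = AmpliconPanel([amp], version="one")
        off = amp.fwd_primer_len + 5
        alt = "A" if amp.base_at(off) != "A" else "C"
        fq = simulate_fastq(
            sub, 1000, tmp_path / "f.fastq", seed=4, error_rate=0.0, sd_q=0.0,
            forced_alt=[(amp.name, off, alt, 10)],
        )
        assigned = []
        for read in read_fastq(fq, "S"):
            t = trim_read(read)
            if t:
                hit = assign_read(t, sub)
                if hit:
                    assigned.append(hit)
        cols = {c.offset: c for c in build_pileup(assigned, sub)}
        (obs,) = compute_af(cols[off])
        assert obs.allele == alt
        assert obs.af == pytest.approx(0.01, abs=1e-6)


class TestSerialCohort:
    def test_truth_table_bookkeeping(self, small_panel, small_catalogue):
        panel, _ = small_panel
        _, candidates = small_catalogue
        counts, sheet, truth = simulate_serial_cohort(
            panel, candidates, n_patients=3, samples_per_patient=2,
            n_recurrent=2, n_sporadic=1, seed=11,
        )
        # 2 recurrent x 2 time points + 1 sporadic x 1 = 5 rows per patient
        assert len(truth) == 3 * 5
        per_mut = truth.groupby(["patient", "chrom", "pos", "alt"]).size()
        assert set(per_mut) == {1, 2}
        assert len(sheet) == 6
        assert (truth["true_maf"] >= 0.005).all()
        assert set(counts["sample"]) == set(sheet["sample_id"])

    def test_recurrent_maf_floor(self, small_panel, small_catalogue):
        panel, _ = small_panel
        _, candidates = small_catalogue
        _, _, truth = simulate_serial_cohort(panel, candidates, n_patients=4,
                                             seed=12)
        assert (truth["true_maf"] >= 0.005).all()
        rec = truth[truth.recurrence == "recurrent"]["true_maf"]
        spo = truth[truth.recurrence == "sporadic"]["true_maf"]
        assert len(rec) and len(spo)
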