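"""Recurrence classification, cohort summaries and replicate concordance."""

import numpy as np
import pandas as pd
import pytest

from ampcall.longitudinal import (
    SerialSampleSet,
    classify_recurrence,
    replicate_concordance,
    summarize_cohort,
    trajectory_table,
)


def _calls(rows):
    base = {"status": "annotated", "gene": "G", "af": 0.02, "ref": "C", "allele": "T"}
    return pd.DataFrame([{**base, **r} for r in rows])


def _sheet(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "time_index", "clinical_status",
                       "replicate_of"]
    ).assign(replicate_of="")


class TestRecurrence:
    def setup_method(self):
        self.patient = SerialSampleSet(
            "P1", [("s1", 1, "stable"), ("s2", 2, "progressive"),
                   ("s3", 3, "progressive"), ("s4", 4, "unknown")]
        )

    def test_present_in_two_of_two(self):
        p = SerialSampleSet("P", [("a", 1, "stable"), ("b", 2, "stable")])
        calls = _calls([{"sample": "a", "chrom": "c", "pos": 10},
                        {"sample": "b", "chrom": "c", "pos": 10}])
        assert classify_recurrence(p, calls) == {("c", 10, "C", "T"): "recurrent"}

    def test_single_time_point_is_sporadic(self):
        calls = _calls([{"sample": "s2", "chrom": "c", "pos": 10}])
        assert classify_recurrence(self.patient, calls) == {
            ("c", 10, "C", "T"): "sporadic"
        }

    def test_nonconsecutive_presence_counts_as_recurrent(self):
        calls = _calls([{"sample": "s1", "chrom": "c", "pos": 10},
                        {"sample": "s3", "chrom": "c", "pos": 10}])
        assert classify_recurrence(self.patient, calls) == {
            ("c", 10, "C", "T"): "recurrent"
        }

    def test_single_sample_patient_sentinel(self):
        p = SerialSampleSet("P", [("only", 1, "stable")])
        assert classify_recurrence(p, _calls([{"sample": "only", "chrom": "c",
                                               "pos": 1}])) is None

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        rows = []
        for pos in range(1, 21):
            for s in rng.choice(["s1", "s2", "s3", "s4"],
                                size=rng.integers(1, 5), replace=False):
                rows.append({"sample": s, "chrom": "c", "pos": pos})
        calls = _calls(rows)
        classes = classify_recurrence(self.patient, calls)
        n_keys = calls.drop_duplicates(["chrom", "pos", "ref", "allele"]).shape[0]
        labels = pd.Series(list(classes.values()))
        assert (labels == "recurrent").sum() + (labels == "sporadic").sum() == n_keys


class TestCohortSummary:
    def test_mean_mutations_per_sample(self):
        sheet = _sheet([("a", "P1", 1, "stable", ""), ("b", "P1", 2, "stable", ""),
                        ("c", "P2", 1, "stable", "")])
        rows = []
        for s, n in (("a", 2), ("b", 3), ("c", 2)):
            rows += [{"sample": s, "chrom": "c", "pos": i} for i in range(n)]
        summary = summarize_cohort(_calls(rows), sheet)
        assert summary.mean_mutations_per_sample == pytest.approx(7 / 3, abs=5e-3)

    def test_af_statistics_constant(self):
        sheet = _sheet([("a", "P1", 1, "stable", "")])
        calls = _calls([{"sample": "a", "chrom": "c", "pos": i, "af": 0.01}
                        for i in range(4)])
        s = summarize_cohort(calls, sheet)
        assert s.af_median == s.af_min == s.af_max == pytest.approx(0.01)

    def test_sample_order_invariance(self):
        sheet = _sheet([("a", "P1", 1, "stable", ""), ("b", "P1", 2, "stable", "")])
        calls = _calls([{"sample": "a", "chrom": "c", "pos": 1, "af": 0.02},
                        {"sample": "b", "chrom": "c", "pos": 1, "af": 0.05},
                        {"sample": "b", "chrom": "c", "pos": 7, "af": 0.01}])
        s1 = summarize_cohort(calls, sheet)
        s2 = summarize_cohort(calls.iloc[::-1].reset_index(drop=True),
                              sheet.iloc[::-1].reset_index(drop=True))
        assert s1.mean_mutations_per_sample == s2.mean_mutations_per_sample
        assert s1.af_median == s2.af_median

    def test_recurrent_higher_af_detected_by_wilcoxon(self):
        """Simulated cohort where recurrent mutations have higher MAFs than
        sporadic ones: one-sided Wilcoxon rank-sum is significant."""
        rng = np.random.default_rng(7)
        sheet_rows, call_rows = [], []
        for p in range(50):
            pid = f"P{p}"
            s1, s2 = f"{pid}a", f"{pid}b"
            sheet_rows += [(s1, pid, 1, "stable", ""), (s2, pid, 2, "stable", "")]
            af_rec = float(np.exp(rng.normal(np.log(0.03), 0.4)))
            af_spo = float(np.exp(rng.normal(np.log(0.008), 0.4)))
            call_rows += [
                {"sample": s1, "chrom": "c", "pos": 2 * p, "af": af_rec},
                {"sample": s2, "chrom": "c", "pos": 2 * p, "af": af_rec},
                {"sample": s1, "chrom": "c", "pos": 2 * p + 1, "af": af_spo},
            ]
        summary = summarize_cohort(_calls(call_rows), _sheet(sheet_rows),
                                   alternative="greater")
        assert summary.recurrent_vs_sporadic_p < 0.05
        assert summary.recurrent_af_median > summary.sporadic_af_median


class TestConcordance:
    def test_identical_call_sets(self):
        calls = _calls([{"sample": "r1", "chrom": "c", "pos": i, "af": 0.01 * (i + 1)}
                        for i in range(5)])
        res = replicate_concordance(calls, calls.assign(sample="r2"))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.n_shared == 5 and res.n_unique_1 == res.n_unique_2 == 0

    def test_disjoint_sets_bookkeeping(self):
        c1 = _calls([{"sample": "r1", "chrom": "c", "pos": i, "af": 0.02 + 0.01 * i}
                     for i in range(3)])
        c2 = _calls([{"sample": "r2", "chrom": "c", "pos": 10 + i,
                      "af": 0.02 + 0.01 * i} for i in range(3)])
        res = replicate_concordance(c1, c2, mode="union")
        assert res.n_shared == 0
        assert res.n_unique_1 + res.n_unique_2 == 6
        assert res.pearson_r is not None  # computed over the 6-key union
        res_int = replicate_concordance(c1, c2, mode="intersection")
        assert res_int.pearson_r is None  # < 3 shared keys

    def test_too_few_shared_keys_unavailable(self):
        c1 = _calls([{"sample": "r1", "chrom": "c", "pos": 1}])
        res = replicate_concordance(c1, c1.assign(sample="r2"))
        assert res.pearson_r is None and res.spearman_rho is None


def test_trajectory_table_long_format():
    sheet = _sheet([("a", "P1", 1, "stable", ""), ("b", "P1", 2, "progressive", "")])
    calls = _calls([
        {"sample": "a", "chrom": "c", "pos": 5, "af": 0.02},
        {"sample": "b", "chrom": "c", "pos": 5, "af": 0.06},
        {"sample": "b", "chrom": "c", "pos": 9, "af": 0.01},
    ])
    table = trajectory_table(calls, sheet)
    assert list(table.columns) == ["patient", "mutation", "gene", "time_index",
                                   "af", "clinical_status", "recurrence"]
    shared = table[table["mutation"] == "c:5C>T"]
    assert list(shared["recurrence"].unique()) == ["recurrent"]
    assert list(shared.sort_values("time_index")["af"]) == [0.02, 0.06]
    assert (table.loc[table["mutation"] == "c:9C>T", "recurrence"] == "sporadic").all()
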