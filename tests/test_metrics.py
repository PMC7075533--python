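"""Mishit metrics, CDR3 overlap partitions, Top-N and speed accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from airrbench import metrics as mt, synthetic_data as sd
from airrbench.germline import SynonymMap, build_synonym_map
from airrbench.models import AnnotatorProfile, SimulationConfig

from test_preprocess import table_from


def truth_table(v_genes, prefix="r"):
    rows = [{"sequence_id": f"{prefix}{i}", "v_call": g} for i, g in enumerate(v_genes)]
    return table_from(rows)


def annotation_table(v_genes, prefix="r"):
    return truth_table(v_genes, prefix=prefix)


class TestPrimaryCall:
    def test_first_of_multiple(self):
        row = pd.Series({"v_call": "IGHV3-53,IGHV3-66"})
        assert mt.primary_call(row, "V") == "IGHV3-53"

    def test_no_call(self):
        assert mt.primary_call(pd.Series({"j_call": ""}), "J") == mt.NO_CALL
        assert mt.primary_call(pd.Series({"j_call": None}), "J") == mt.NO_CALL

    def test_synonym_canonicalized(self):
        syn = SynonymMap(level="gene", mapping={"IGHV9-99": "IGHV3-30"})
        row = pd.Series({"v_call": "IGHV9-99*01"})
        assert mt.primary_call(row, "V", syn) == "IGHV3-30"


class TestMishitFrequency:
    def test_one_in_five(self):
        truth = truth_table(["IGHV1-A", "IGHV1-A", "IGHV1-B", "IGHV1-B", "IGHV1-B"])
        ann = annotation_table(["IGHV1-A", "IGHV1-B", "IGHV1-B", "IGHV1-B", "IGHV1-B"])
        s = mt.mishit_frequency(ann, truth, "V")
        assert (s.K, s.N) == (1, 5)
        assert s.frequency == pytest.approx(0.2)

    def test_all_correct(self):
        truth = truth_table(["IGHV1-1"] * 4)
        s = mt.mishit_frequency(annotation_table(["IGHV1-1"] * 4), truth, "V")
        assert s.frequency == 0.0

    def test_no_calls_gives_missing_frequency(self):
        truth = truth_table(["IGHV1-1"] * 3)
        ann = annotation_table([""] * 3)
        s = mt.mishit_frequency(ann, truth, "V")
        assert s.N == 0 and s.frequency is None

    def test_unknown_sequence_id_rejected(self):
        truth = truth_table(["IGHV1-1"])
        ann = annotation_table(["IGHV1-1"], prefix="zzz")
        with pytest.raises(mt.DataError):
            mt.mishit_frequency(ann, truth, "V")

    def test_synonym_not_a_mishit(self):
        truth = truth_table(["IGHV3-30"])
        ann = annotation_table(["IGHV9-99"])
        syn = SynonymMap(level="gene", mapping={"IGHV9-99": "IGHV3-30"})
        assert mt.mishit_frequency(ann, truth, "V", syn).K == 0

    @pytest.mark.parametrize("p", [0.0, 0.05, 0.3, 1.0])
    def test_injected_rate_recovery(self, plain_reference, p):
        n = 2500
        truth = sd.generate_repertoire(
            plain_reference, SimulationConfig(n_base=n, n_mutated=0, seed=21))
        table = sd.emulate_annotator(
            truth,
            AnnotatorProfile(tool_label="t", mishit_rate_v=p, granularity="gene",
                             seed=23),
            plain_reference)
        syn = build_synonym_map(plain_reference, "gene")
        s = mt.mishit_frequency(table, truth, "V", syn)
        assert s.N == n
        assert abs(s.frequency - p) <= 3 * math.sqrt(p * (1 - p) / n)


class TestSubgroupMishits:
    def test_partition_identity(self):
        truth = truth_table(["IGHV3-1", "IGHV3-1", "IGHV3-2", "IGHV3-2",
                             "IGHV1-1", "IGHV1-2"])
        ann = annotation_table(["IGHV3-1", "IGHV3-2", "IGHV3-2", "IGHV3-2",
                                "IGHV1-1", "IGHV1-2"])
        rows = mt.subgroup_mishit_frequencies(ann, truth, "V")
        summary = mt.mishit_frequency(ann, truth, "V")
        assert sum(r.W for r in rows) == summary.K
        assert sum(r.X for r in rows) == summary.N

    def test_quarter_frequency(self):
        truth = truth_table(["IGHV3-1"] * 4)
        ann = annotation_table(["IGHV3-1", "IGHV3-1", "IGHV3-1", "IGHV1-9"])
        (row,) = mt.subgroup_mishit_frequencies(ann, truth, "V")
        assert row.subgroup == "IGHV3"
        assert row.frequency == pytest.approx(0.25)

    def test_errors_concentrated_in_one_subgroup(self):
        truth = truth_table(["IGHV3-1", "IGHV3-1", "IGHV1-1", "IGHV1-1"])
        ann = annotation_table(["IGHV4-4", "IGHV4-4", "IGHV1-1", "IGHV1-1"])
        rows = {r.subgroup: r for r in mt.subgroup_mishit_frequencies(ann, truth, "V")}
        assert rows["IGHV3"].frequency == 1.0
        assert rows["IGHV1"].frequency == 0.0


class TestConfusionMatrix:
    def test_row_fractions(self):
        truth = truth_table(["IGHV1-A"] * 4)
        ann = annotation_table(["IGHV1-A", "IGHV1-A", "IGHV1-A", "IGHV1-B"])
        m = mt.confusion_matrix(ann, truth, "V")
        assert m.loc["IGHV1-A", "IGHV1-A"] == pytest.approx(0.75)
        assert m.loc["IGHV1-A", "IGHV1-B"] == pytest.approx(0.25)

    def test_perfect_annotator_identity(self):
        truth = truth_table(["IGHV1-1", "IGHV2-2", "IGHV3-3"])
        m = mt.confusion_matrix(annotation_table(["IGHV1-1", "IGHV2-2", "IGHV3-3"]),
                                truth, "V")
        assert np.allclose(np.diag(m.values), 1.0)

    def test_rows_sum_to_one_with_no_call(self):
        truth = truth_table(["IGHV1-1", "IGHV1-1", "IGHV2-2"])
        ann = annotation_table(["IGHV1-1", "", "IGHV1-1"])
        m = mt.confusion_matrix(ann, truth, "V")
        assert np.allclose(m.sum(axis=1), 1.0)
        assert mt.NO_CALL in m.columns

    def test_confusion_pair_recovery(self, plain_reference):
        # a targeted confusion at the published IGHV3-66 -> IGHV3-53 rate
        p = 0.49
        genes = plain_reference.gene_names("V")
        source, sink = genes[0], genes[1]
        truth = sd.generate_repertoire(
            plain_reference, SimulationConfig(n_base=2000, n_mutated=0, seed=31))
        table = sd.emulate_annotator(
            truth,
            AnnotatorProfile(tool_label="t", granularity="gene", seed=33,
                             confusion_pairs={source: (sink, p)}),
            plain_reference)
        m = mt.confusion_matrix(table, truth, "V")
        n_source = sum(1 for t in truth if t.true_v_gene == source)
        observed = m.loc[source, sink]
        assert abs(observed - p) <= 3 * math.sqrt(p * (1 - p) / n_source)

    def test_consistency_with_mishit_frequency(self, plain_reference):
        truth = sd.generate_repertoire(
            plain_reference, SimulationConfig(n_base=600, n_mutated=0, seed=41))
        table = sd.emulate_annotator(
            truth,
            AnnotatorProfile(tool_label="t", mishit_rate_v=0.25, granularity="gene",
                             seed=43),
            plain_reference)
        m = mt.confusion_matrix(table, truth, "V")
        s = mt.mishit_frequency(table, truth, "V")
        # trace-weighted accuracy of the confusion matrix complements K/N
        true_counts = pd.Series([t.true_v_gene for t in truth]).value_counts()
        correct = sum(m.loc[g, g] * true_counts[g] for g in m.index)
        assert 1 - correct / s.N == pytest.approx(s.frequency)


class TestCdr3Overlap:
    def test_two_set_example(self):
        part = mt.cdr3_overlap({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert part.region_counts[frozenset({"A", "B"})] == 2
        assert part.percentage("A", {"A", "B"}) == pytest.approx(66.7, abs=0.05)
        assert part.percentage("A", {"A"}) == pytest.approx(33.3, abs=0.05)

    def test_identical_sets(self):
        part = mt.cdr3_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        assert part.percentage("A", {"A", "B"}) == 100.0
        assert part.percentage("B", {"A", "B"}) == 100.0

    def test_disjoint_sets(self):
        part = mt.cdr3_overlap({"A": {"x"}, "B": {"y"}})
        assert part.shared_by_all == 0
        assert part.percentage("A", {"A"}) == 100.0

    def test_single_tool_rejected(self):
        with pytest.raises(ValueError):
            mt.cdr3_overlap({"A": {"x"}})

    def test_per_tool_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        pool = [f"CDR{i}" for i in range(60)]
        sets = {lab: set(rng.choice(pool, size=rng.integers(5, 50), replace=False))
                for lab in "ABC"}
        part = mt.cdr3_overlap(sets)
        for tool, regions in part.per_tool_percentages().items():
            assert sum(regions.values()) == pytest.approx(100.0, abs=0.1)


class TestTopN:
    def _table(self, freq):
        rows = []
        for cdr3, n in freq.items():
            rows.extend({"cdr3_aa": cdr3} for _ in range(n))
        return table_from(rows)

    def test_lexicographic_tie_break(self):
        table = self._table({"XXXXX": 5, "YYYYY": 3, "ZZZZZ": 3, "WWWWW": 1})
        assert mt.top_n_cdr3(table, 2) == {"XXXXX", "YYYYY"}

    def test_n_exceeds_distinct(self):
        table = self._table({"AAAAA": 2, "BBBBB": 1})
        assert mt.top_n_cdr3(table, 100) == {"AAAAA", "BBBBB"}

    def test_single_mode(self):
        table = self._table({"AAAAA": 3, "BBBBB": 2, "CCCCC": 1})
        assert mt.top_n_cdr3(table, 1) == {"AAAAA"}

    def test_duplicate_count_weighting(self):
        table = table_from([
            {"cdr3_aa": "AAAAA", "duplicate_count": 10},
            {"cdr3_aa": "BBBBB", "duplicate_count": 1},
            {"cdr3_aa": "BBBBB", "duplicate_count": 1},
        ])
        assert mt.top_n_cdr3(table, 1) == {"AAAAA"}


class TestProcessingSpeed:
    @pytest.mark.parametrize("n, minutes, jobs, expected", [
        (1000, 10, 2, 50.0),
        (1000, 10, 1, 100.0),
    ])
    def test_formula(self, n, minutes, jobs, expected):
        assert mt.processing_speed(n, minutes, jobs).speed == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mt.processing_speed(1000, 10, 0)


class TestAnnotationDiscrepancy:
    def test_hand_enumeration(self):
        a = table_from([
            {"sequence_id": "s1", "cdr3_aa": "AAAAA", "v_call": "IGHV1-1"},
            {"sequence_id": "s2", "cdr3_aa": "BBBBB", "v_call": "IGHV1-1"},
            {"sequence_id": "s3", "cdr3_aa": "CCCCC", "v_call": "IGHV1-1"},
        ])
        b = table_from([
            {"sequence_id": "s1", "cdr3_aa": "AAAAA", "v_call": "IGHV1-1"},
            {"sequence_id": "s2", "cdr3_aa": "XXXXX", "v_call": "IGHV1-1"},
            {"sequence_id": "s3", "cdr3_aa": "YYYYY", "v_call": "IGHV2-2"},
        ])
        c = mt.annotation_discrepancy(a, b, "a", "b")
        assert c.n_inputs == 3
        # BBBBB and CCCCC absent from b's CDR3 set; XXXXX and YYYYY from a's
        assert c.nonoverlap_a == 2
        assert c.nonoverlap_b == 2
        assert c.same_vdj_diff_cdr3 == 1  # s2: same VDJ, different CDR3
        assert c.diff_vdj_diff_cdr3 == 1  # s3: different V call too

    def test_percentages_of_printed_counts(self):
        c = mt.DiscrepancyCounts(
            n_inputs=759_505, label_a="igblast", label_b="hvquest",
            nonoverlap_a=51_791, nonoverlap_b=14_844,
            same_vdj_diff_cdr3=7_735, diff_vdj_diff_cdr3=1_248)
        pct = c.percentages()
        assert pct["nonoverlap_igblast"] == 6.82
        assert pct["nonoverlap_hvquest"] == 1.95
        assert round(pct["same_vdj_diff_cdr3"]) == 1
        assert pct["diff_vdj_diff_cdr3"] == 0.16
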