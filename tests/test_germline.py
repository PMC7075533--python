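"""Reference set intersection, change tabulation and synonym grouping."""

import datetime as dt
from itertools import combinations

import numpy as np
import pytest

from airrbench import germline as gl
from airrbench.airr_io import FastaHeaderError, read_reference_fasta
from airrbench.models import ChangeEvent, ChangeLog, GermlineAllele, ReferenceSet

from conftest import make_reference, sets_from_regions


class TestReadReferenceFasta:
    def test_parses_imgt_style_header(self, tmp_path):
        path = tmp_path / "ref.fasta"
        path.write_text(">X1|IGHV1-18*01|Homo sapiens|F\nCAGGT\n")
        ref = read_reference_fasta(path)
        (a,) = ref.alleles
        assert a.allele_name == "IGHV1-18*01"
        assert a.gene_name == "IGHV1-18"
        assert a.subgroup_name == "IGHV1"
        assert a.functionality == "F"
        assert a.nt_sequence == "CAGGT"
        assert not a.orphon

    def test_orphon_flag(self, tmp_path):
        path = tmp_path / "ref.fasta"
        path.write_text(
            ">X1|IGHV1/OR15-1*01|Homo sapiens|ORF\nCAGGT\n"
            ">X2|IGHV1-69D*01|Homo sapiens|F\nCAGGA\n"
        )
        ref = read_reference_fasta(path)
        assert all(a.orphon for a in ref.alleles)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with caplog.at_level("WARNING"):
            ref = read_reference_fasta(path)
        assert ref.alleles == []
        assert any("no records" in r.message for r in caplog.records)

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">IGHV1-18*01\nCAGGT\n")
        with pytest.raises(FastaHeaderError):
            read_reference_fasta(path)

    def test_round_trip(self, tmp_path, reference):
        from airrbench.airr_io import write_reference_fasta
        path = tmp_path / "rt.fasta"
        write_reference_fasta(reference, path)
        back = read_reference_fasta(path)
        assert [(a.allele_name, a.nt_sequence) for a in back.alleles] == \
               [(a.allele_name, a.nt_sequence) for a in reference.alleles]


def brute_force_regions(items_by_label):
    """Independent oracle: enumerate every subset and count exact members."""
    labels = list(items_by_label)
    regions = {}
    for r in range(1, len(labels) + 1):
        for group in combinations(labels, r):
            inside = set.intersection(*(set(items_by_label[g]) for g in group))
            outside = set().union(
                *(set(items_by_label[l]) for l in labels if l not in group),
                set(),
            )
            count = len(inside - outside)
            if count:
                regions[frozenset(group)] = count
    return regions


class TestIntersectReferences:
    def test_three_set_example(self):
        names = {"A": ["g1", "g2", "g3"], "B": ["g2", "g3", "g4"], "C": ["g3"]}
        sets = [make_reference(lab, [f"IGHV1-{g[1]}" for g in genes])
                for lab, genes in names.items()]
        table = gl.intersect_references(sets, level="gene")
        assert table.shared_by_all == 1
        assert table.union_size == 4
        assert table.shared_percentage == 25

    def test_identical_sets(self):
        genes = [f"IGHV1-{i}" for i in range(1, 6)]
        table = gl.intersect_references(
            [make_reference("A", genes), make_reference("B", genes)], level="gene")
        assert table.shared_percentage == 100
        assert table.exclusive("A") == 0 and table.exclusive("B") == 0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            gl.intersect_references([make_reference("A", ["IGHV1-1"])])

    def test_region_sums_match_totals_and_union(self):
        rng = np.random.default_rng(42)
        labels = ["w", "x", "y", "z"]
        for _ in range(20):
            pool = [f"IGHV1-{i}" for i in range(1, 30)]
            items = {lab: list(rng.choice(pool, size=rng.integers(1, 20),
                                          replace=False)) for lab in labels}
            sets = [make_reference(lab, genes) for lab, genes in items.items()]
            table = gl.intersect_references(sets, level="gene")
            oracle = brute_force_regions({lab: set(v) for lab, v in items.items()})
            assert table.region_counts == oracle
            assert table.union_size == len(set().union(*map(set, items.values())))
            for lab in labels:
                contained = sum(c for region, c in table.region_counts.items()
                                if lab in region)
                assert contained == table.totals[lab]

    def test_gene_type_filter_and_levels(self, reference):
        other = ReferenceSet(
            label="other",
            alleles=[a for a in reference.alleles if a.gene_type != "D"],
        )
        table = gl.intersect_references([reference.relabel("ref"), other],
                                        level="gene", gene_type_filter="V")
        assert table.shared_percentage == 100
        nt = gl.intersect_references([reference.relabel("ref"), other],
                                     level="nt_sequence")
        assert nt.union_size > 0


class TestTabulateChanges:
    def _log(self, spec):
        events = []
        for date, ctype, n in spec:
            events.extend(
                ChangeEvent(release_date=date, change_type=ctype, target=f"g{i}")
                for i in range(n)
            )
        return ChangeLog(events=events)

    def test_per_type_counts(self):
        log = self._log([
            (dt.date(2015, 1, 1), "gene_removal", 2),
            (dt.date(2015, 6, 1), "gene_addition", 3),
        ])
        summary = gl.tabulate_changes(log)
        assert summary.per_type["gene_removal"] == 2
        assert summary.per_type["gene_addition"] == 3
        assert summary.total == 5

    def test_empty_window(self):
        log = self._log([(dt.date(2015, 1, 1), "gene_removal", 2)])
        summary = gl.tabulate_changes(log, dt.date(2016, 1, 1), dt.date(2017, 1, 1))
        assert summary.total == 0

    def test_window_additivity(self):
        log = self._log([
            (dt.date(2014, 1, 1), "allele_addition", 4),
            (dt.date(2015, 1, 1), "sequence_change", 2),
            (dt.date(2016, 1, 1), "metadata_change", 5),
        ])
        left = gl.tabulate_changes(log, dt.date(2014, 1, 1), dt.date(2014, 12, 31))
        right = gl.tabulate_changes(log, dt.date(2015, 1, 1), dt.date(2016, 12, 31))
        both = gl.tabulate_changes(log, dt.date(2014, 1, 1), dt.date(2016, 12, 31))
        for ctype in left.per_type:
            assert left.per_type[ctype] + right.per_type[ctype] == both.per_type[ctype]
        assert left.total + right.total == both.total

    def test_cumulative_non_decreasing(self):
        log = self._log([
            (dt.date(2014, 1, 1), "allele_addition", 1),
            (dt.date(2015, 1, 1), "allele_addition", 3),
        ])
        cum = gl.tabulate_changes(log).cumulative()
        assert list(cum["allele_addition"]) == [1, 4]


class TestUpdateIntervalStats:
    def test_constant_intervals_and_counts(self):
        events = []
        for week in (0, 13, 26):
            date = dt.date(2015, 1, 1) + dt.timedelta(weeks=week)
            events.extend(
                ChangeEvent(release_date=date, change_type="allele_addition",
                            target=f"g{week}-{i}")
                for i in range(4)
            )
        stats = gl.update_interval_stats(ChangeLog(events=events))
        assert stats.mean_interval_weeks == pytest.approx(13.0)
        assert stats.mean_changes_per_update == pytest.approx(4.0)

    def test_single_release_rejected(self):
        log = ChangeLog(events=[ChangeEvent(dt.date(2015, 1, 1),
                                            "gene_addition", "g")])
        with pytest.raises(ValueError):
            gl.update_interval_stats(log)

    def test_p90_nearest_rank(self):
        # releases spaced 1..10 weeks apart: p90 of the intervals is 9
        dates = [dt.date(2015, 1, 1)]
        for gap in range(1, 11):
            dates.append(dates[-1] + dt.timedelta(weeks=gap))
        events = [ChangeEvent(d, "gene_addition", f"g{i}")
                  for i, d in enumerate(dates)]
        stats = gl.update_interval_stats(ChangeLog(events=events))
        assert stats.p90_interval_weeks == pytest.approx(9.0)


class TestBuildSynonymMap:
    def _ref(self, gene_to_seq):
        alleles = [
            GermlineAllele.from_name(f"{gene}*01", "V", seq)
            for gene, seq in gene_to_seq.items()
        ]
        return ReferenceSet(label="syn", alleles=alleles)

    def test_lexicographically_smallest_is_canonical(self):
        ref = self._ref({"IGHV9-99": "ACGT", "IGHV3-30": "ACGT"})
        syn = gl.build_synonym_map(ref, level="gene")
        assert syn.canonical("IGHV9-99") == "IGHV3-30"
        assert syn.canonical("IGHV3-30") == "IGHV3-30"

    def test_no_duplicates_identity(self):
        ref = self._ref({"IGHV1-1": "ACGT", "IGHV1-2": "TTTT"})
        syn = gl.build_synonym_map(ref, level="gene")
        assert len(syn) == 0
        assert syn.canonical("IGHV1-1") == "IGHV1-1"
        assert syn.canonical("IGHV5-555") == "IGHV5-555"  # unknown -> itself

    def test_three_way_group(self):
        ref = self._ref({"IGHV2-2": "AAAA", "IGHV1-8": "AAAA", "IGHV1-18": "AAAA"})
        syn = gl.build_synonym_map(ref, level="gene")
        assert {syn.canonical(g) for g in ("IGHV2-2", "IGHV1-8", "IGHV1-18")} == \
               {"IGHV1-18"}

    def test_idempotent(self, reference):
        syn = gl.build_synonym_map(reference, level="gene")
        for gene in reference.gene_names():
            once = syn.canonical(gene)
            assert syn.canonical(once) == once

    def test_allele_level(self):
        alleles = [
            GermlineAllele.from_name("IGHV1-1*01", "V", "ACGT"),
            GermlineAllele.from_name("IGHV1-1*02", "V", "ACGA"),
            GermlineAllele.from_name("IGHV2-9*01", "V", "ACGT"),
        ]
        syn = gl.build_synonym_map(ReferenceSet(label="s", alleles=alleles),
                                   level="allele")
        assert syn.canonical("IGHV2-9*01") == "IGHV1-1*01"
        assert syn.canonical("IGHV1-1*02") == "IGHV1-1*02"


class TestPrintedCountFixtures:
    """Fixtures realizing published germline-intersection region counts."""

    def test_shared_v_gene_percentage(self):
        # three tools with 55/104/97 V genes, 4/29/29 tool-exclusive and 44
        # shared by all: the unique solution of the region system puts the
        # union at 137 and the shared fraction at 32%
        regions = {
            ("igsim",): 4, ("igblast",): 29, ("mixcr",): 29,
            ("igsim", "igblast"): 7, ("igsim", "mixcr"): 0,
            ("igblast", "mixcr"): 24,
            ("igsim", "igblast", "mixcr"): 44,
        }
        names = sets_from_regions(regions)
        sets = [make_reference(lab, genes) for lab, genes in names.items()]
        table = gl.intersect_references(sets, level="gene")
        assert table.totals == {"igsim": 55, "igblast": 104, "mixcr": 97}
        assert table.union_size == 137
        assert table.shared_by_all == 44
        assert table.shared_percentage == 32
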