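"""Accuracy, overlap and throughput metrics for annotation benchmarking.

Accuracy is measured against the known originating germline of each
simulated read: a *hit* assigns a read to its true gene, a *mishit* to any
other gene.  The cumulative mishit frequency is K/N — mishits over total
annotations of that gene type — and per-subgroup frequencies are W/X within
each true-gene subgroup.  Confusion matrices characterize which genes
absorb the misassignments.  CDR3 agreement between tools is quantified as
exact-string overlap partitions of unique CDR3 sets, per-read discrepancy
rates, and Top-N most-frequent CDR3 selections.  Throughput uses the
processing-speed formula sequences / (minutes × jobs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .germline import SynonymMap
from .models import GroundTruthRearrangement, split_calls, strip_allele

__all__ = [
    "MishitSummary",
    "SubgroupMishitRow",
    "OverlapPartition",
    "SpeedRecord",
    "DiscrepancyCounts",
    "primary_call",
    "mishit_frequency",
    "subgroup_mishit_frequencies",
    "confusion_matrix",
    "cdr3_overlap",
    "top_n_cdr3",
    "processing_speed",
    "annotation_discrepancy",
]

NO_CALL = "no call"

_CALL_COLUMN = {"V": "v_call", "D": "d_call", "J": "j_call"}
_TRUE_FIELD = {"V": "true_v_gene", "D": "true_d_gene", "J": "true_j_gene"}


class DataError(ValueError):
    """Annotations referencing reads absent from the ground truth."""


def primary_call(
    record: Mapping | pd.Series,
    gene_type: str,
    synonyms: SynonymMap | None = None,
) -> str:
    """First assigned gene of a record, canonicalized; "no call" when empty.

    When a tool reports multiple candidate genes, the first one is the
    alignment that counts.
    """
    calls = split_calls(record.get(_CALL_COLUMN[gene_type]))
    if not calls:
        return NO_CALL
    name = strip_allele(calls[0])
    return synonyms.canonical(name) if synonyms else name


def _truth_genes(
    truth: Iterable[GroundTruthRearrangement] | pd.DataFrame,
    gene_type: str,
    synonyms: SynonymMap | None,
) -> dict[str, str]:
    """sequence_id -> canonical true gene name."""
    out: dict[str, str] = {}
    if isinstance(truth, pd.DataFrame):
        col = _CALL_COLUMN[gene_type]
        for sid, call in zip(truth["sequence_id"], truth[col]):
            calls = split_calls(call)
            if not calls:
                continue
            name = strip_allele(calls[0])
            out[str(sid)] = synonyms.canonical(name) if synonyms else name
        return out
    for t in truth:
        name = strip_allele(getattr(t, _TRUE_FIELD[gene_type]))
        out[t.sequence_id] = synonyms.canonical(name) if synonyms else name
    return out


def _paired_calls(
    annotations: pd.DataFrame,
    truth,
    gene_type: str,
    synonyms: SynonymMap | None,
) -> list[tuple[str, str]]:
    """(true_gene, assigned) pairs per annotated read; assigned may be "no call"."""
    true_by_id = _truth_genes(truth, gene_type, synonyms)
    pairs = []
    for _, row in annotations.iterrows():
        sid = str(row["sequence_id"])
        if sid not in true_by_id:
            raise DataError(f"annotation for unknown sequence_id {sid!r}")
        pairs.append((true_by_id[sid], primary_call(row, gene_type, synonyms)))
    return pairs


@dataclass(frozen=True)
class MishitSummary:
    """Cumulative mishit frequency K/N for one tool and gene type."""

    gene_type: str
    K: int
    N: int

    @property
    def frequency(self) -> float | None:
        """K/N, or None when no annotations carry a call of this type."""
        if self.N == 0:
            return None
        return self.K / self.N


def mishit_frequency(
    annotations: pd.DataFrame,
    truth,
    gene_type: str = "V",
    synonyms: SynonymMap | None = None,
) -> MishitSummary:
    """Mishit frequency K/N at gene level.

    N counts reads with a call of the requested type; K counts those whose
    canonicalized primary call differs from the canonicalized true gene.
    No-call reads are excluded from both.
    """
    pairs = _paired_calls(annotations, truth, gene_type, synonyms)
    called = [(t, a) for t, a in pairs if a != NO_CALL]
    K = sum(1 for t, a in called if a != t)
    return MishitSummary(gene_type=gene_type, K=K, N=len(called))


@dataclass(frozen=True)
class SubgroupMishitRow:
    """Mishit frequency W/X within one true-gene subgroup."""

    subgroup: str
    W: int
    X: int

    @property
    def frequency(self) -> float:
        return self.W / self.X


def _subgroup_of(gene: str) -> str:
    # IGHV3-53 -> IGHV3; IGHJ4 -> IGHJ4 (J genes are their own subgroup)
    import re
    m = re.match(r"^(IG[HKL][VDJ]\d*)", gene)
    return m.group(1) if m else gene


def subgroup_mishit_frequencies(
    annotations: pd.DataFrame,
    truth,
    gene_type: str = "V",
    synonyms: SynonymMap | None = None,
) -> list[SubgroupMishitRow]:
    """Per-subgroup mishit rows keyed by the TRUE gene's subgroup.

    X counts annotations whose true gene falls in the subgroup (no-call
    reads excluded), W the mishits among them; subgroups with X = 0 are
    omitted.  Summed over subgroups, W and X recover the cumulative K and N.
    """
    pairs = _paired_calls(annotations, truth, gene_type, synonyms)
    acc: dict[str, list[int]] = {}
    for t, a in pairs:
        if a == NO_CALL:
            continue
        sg = _subgroup_of(t)
        w_x = acc.setdefault(sg, [0, 0])
        w_x[1] += 1
        if a != t:
            w_x[0] += 1
    return [
        SubgroupMishitRow(subgroup=sg, W=w, X=x)
        for sg, (w, x) in sorted(acc.items())
    ]


def confusion_matrix(
    annotations: pd.DataFrame,
    truth,
    gene_type: str = "V",
    synonyms: SynonymMap | None = None,
) -> pd.DataFrame:
    """Row-normalized confusion matrix: rows true genes, columns assigned.

    Cell (t, a) is the fraction of reads with true gene t assigned gene a;
    a "no call" column absorbs reads without a call, so every row sums to 1.
    """
    pairs = _paired_calls(annotations, truth, gene_type, synonyms)
    if not pairs:
        return pd.DataFrame()
    counts: dict[str, dict[str, int]] = {}
    for t, a in pairs:
        counts.setdefault(t, {})
        counts[t][a] = counts[t].get(a, 0) + 1
    matrix = pd.DataFrame(counts).T.fillna(0)
    matrix = matrix.sort_index()
    assigned_cols = sorted(c for c in matrix.columns if c != NO_CALL)
    if NO_CALL in matrix.columns:
        assigned_cols.append(NO_CALL)
    matrix = matrix[assigned_cols]
    return matrix.div(matrix.sum(axis=1), axis=0)


@dataclass
class OverlapPartition:
    """Exclusive-region partition of per-tool unique CDR3 sets.

    ``per_tool_percentages`` expresses each region as a percentage of the
    owning tool's total unique CDR3 count — the denominator each tool's
    bars are normalized by.
    """

    stage: str
    totals: dict[str, int]
    region_counts: dict[frozenset[str], int]

    @property
    def labels(self) -> list[str]:
        return list(self.totals)

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    @property
    def shared_by_all(self) -> int:
        return self.region_counts.get(frozenset(self.totals), 0)

    def per_tool_percentages(self) -> dict[str, dict[frozenset[str], float]]:
        out: dict[str, dict[frozenset[str], float]] = {}
        for tool, total in self.totals.items():
            rows = {}
            for region, count in self.region_counts.items():
                if tool in region:
                    rows[region] = 100.0 * count / total if total else 0.0
            out[tool] = rows
        return out

    def percentage(self, tool: str, region: Iterable[str]) -> float:
        """One region's share of a tool's unique CDR3s, in percent."""
        total = self.totals[tool]
        count = self.region_counts.get(frozenset(region), 0)
        return 100.0 * count / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, count in sorted(self.region_counts.items(),
                                    key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            row = {"region": "+".join(sorted(region)), "count": count}
            for tool in self.totals:
                row[f"pct_{tool}"] = (
                    round(100.0 * count / self.totals[tool], 1)
                    if tool in region and self.totals[tool] else ""
                )
            rows.append(row)
        return pd.DataFrame(rows)


def cdr3_overlap(
    cdr3_sets: Mapping[str, set[str]],
    stage: str = "preprocessed",
) -> OverlapPartition:
    """Exact-string overlap partition of ≥2 tools' unique CDR3 sets."""
    if len(cdr3_sets) < 2:
        raise ValueError("need at least 2 tools for an overlap partition")
    labels = list(cdr3_sets)
    totals = {lab: len(s) for lab, s in cdr3_sets.items()}
    union = set().union(*cdr3_sets.values())
    region_counts: dict[frozenset[str], int] = {}
    for item in union:
        region = frozenset(lab for lab in labels if item in cdr3_sets[lab])
        region_counts[region] = region_counts.get(region, 0) + 1
    return OverlapPartition(stage=stage, totals=totals, region_counts=region_counts)


def top_n_cdr3(records: pd.DataFrame, n: int = 100) -> set[str]:
    """The n most frequent distinct CDR3s of a (pre-deduplication) table.

    Frequency counts records per distinct ``cdr3_aa``, weighted by
    ``duplicate_count`` when present.  Ties are broken lexicographically;
    if fewer than n distinct CDR3s exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not len(records):
        return set()
    cdr3 = records["cdr3_aa"].fillna("").astype(str)
    weights = (
        pd.to_numeric(records.get("duplicate_count"), errors="coerce").fillna(1)
        if "duplicate_count" in records.columns
        else pd.Series(1, index=records.index)
    )
    freq = weights.groupby(cdr3).sum()
    freq = freq[freq.index != ""]
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return {cdr3 for cdr3, _ in ranked[:n]}


@dataclass(frozen=True)
class SpeedRecord:
    """Throughput of one annotation run: sequences per minute per job."""

    n_sequences: int
    minutes: float
    jobs: int

    @property
    def speed(self) -> float:
        return self.n_sequences / (self.minutes * self.jobs)


def processing_speed(n_sequences: int, minutes: float, jobs: int) -> SpeedRecord:
    """Processing speed = sequences processed / (minutes × jobs)."""
    if n_sequences <= 0 or minutes <= 0 or jobs <= 0:
        raise ValueError("n_sequences, minutes and jobs must all be positive")
    return SpeedRecord(n_sequences=n_sequences, minutes=minutes, jobs=jobs)


@dataclass(frozen=True)
class DiscrepancyCounts:
    """Per-read CDR3 discrepancy between two tools, over a common input set.

    ``nonoverlap_a`` (resp. ``b``) counts input reads whose tool-A (resp.
    tool-B) CDR3 is absent from the other tool's CDR3 set.
    ``same_vdj_diff_cdr3`` counts reads where both tools agree on all three
    gene segments yet report different CDR3s (annotation-algorithm
    differences); ``diff_vdj_diff_cdr3`` counts reads where the gene
    assignments differ too (alignment differences).
    """

    n_inputs: int
    label_a: str
    label_b: str
    nonoverlap_a: int
    nonoverlap_b: int
    same_vdj_diff_cdr3: int
    diff_vdj_diff_cdr3: int

    def percentages(self, ndigits: int = 2) -> dict[str, float]:
        """Each count as a percentage of the total input sequences."""
        if self.n_inputs <= 0:
            raise ValueError("n_inputs must be positive")
        pct = lambda k: round(100.0 * k / self.n_inputs, ndigits)  # noqa: E731
        return {
            f"nonoverlap_{self.label_a}": pct(self.nonoverlap_a),
            f"nonoverlap_{self.label_b}": pct(self.nonoverlap_b),
            "same_vdj_diff_cdr3": pct(self.same_vdj_diff_cdr3),
            "diff_vdj_diff_cdr3": pct(self.diff_vdj_diff_cdr3),
        }


def annotation_discrepancy(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
    synonyms: SynonymMap | None = None,
) -> DiscrepancyCounts:
    """Quantify per-read CDR3 disagreement between two harmonized tables.

    The denominator is the union of input sequence ids seen by either tool.
    """
    ids_a = set(table_a["sequence_id"].astype(str))
    ids_b = set(table_b["sequence_id"].astype(str))
    n_inputs = len(ids_a | ids_b)
    cdr3_a = dict(zip(table_a["sequence_id"].astype(str),
                      table_a["cdr3_aa"].fillna("").astype(str)))
    cdr3_b = dict(zip(table_b["sequence_id"].astype(str),
                      table_b["cdr3_aa"].fillna("").astype(str)))
    set_a = {c for c in cdr3_a.values() if c}
    set_b = {c for c in cdr3_b.values() if c}
    nonoverlap_a = sum(1 for c in cdr3_a.values() if c and c not in set_b)
    nonoverlap_b = sum(1 for c in cdr3_b.values() if c and c not in set_a)

    def _vdj(table: pd.DataFrame) -> dict[str, tuple[str, str, str]]:
        out = {}
        for _, row in table.iterrows():
            out[str(row["sequence_id"])] = tuple(
                primary_call(row, gt, synonyms) for gt in ("V", "D", "J")
            )
        return out

    vdj_a, vdj_b = _vdj(table_a), _vdj(table_b)
    same_vdj = diff_vdj = 0
    for sid in ids_a & ids_b:
        if cdr3_a[sid] and cdr3_b[sid] and cdr3_a[sid] != cdr3_b[sid]:
            if vdj_a[sid] == vdj_b[sid]:
                same_vdj += 1
            else:
                diff_vdj += 1
    return DiscrepancyCounts(
        n_inputs=n_inputs,
        label_a=label_a,
        label_b=label_b,
        nonoverlap_a=nonoverlap_a,
        nonoverlap_b=nonoverlap_b,
        same_vdj_diff_cdr3=same_vdj,
        diff_vdj_diff_cdr3=diff_vdj,
    )
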