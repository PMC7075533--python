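"""Harmonization and preprocessing of per-tool annotation tables.

Tools disagree on CDR3 boundary conventions (with or without the conserved
C/W anchors), naming granularity (gene vs allele) and duplicate germline
names, so annotation tables are first harmonized to a common schema:
core-convention CDR3s, synonym-canonicalized calls, and a uniform
granularity.  Preprocessing then removes non-IgH reads, reads with stop
codons or frame shifts, unproductive reads, orphon-gene assignments, short
or missing CDR3s and singleton CDR3s, and finally deduplicates to unique
CDR3 amino-acid sequences, attributing every removed record to the first
rule that rejects it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .germline import SynonymMap
from .models import split_calls, strip_allele

__all__ = [
    "FilterReport",
    "HarmonizeResult",
    "FILTER_RULES",
    "normalize_cdr3",
    "harmonize",
    "preprocess_filter",
    "alignment_counts",
]

#: Filter rules, applied in this order; each removed record is attributed to
#: the first rule that rejects it.
FILTER_RULES = (
    "non_igh",
    "stop_codon",
    "out_of_frame",
    "unproductive",
    "orphon",
    "cdr3_length",
    "singleton",
    "duplicate",
)


class DataError(ValueError):
    """Tables that violate a cross-table contract (e.g. unknown sequence ids)."""


def normalize_cdr3(cdr3: str, convention: str) -> str:
    """Convert a CDR3 to the core convention (anchors removed).

    ``core`` input is returned unchanged.  ``anchored`` input must begin
    with the conserved cysteine and end with the conserved tryptophan, both
    of which are stripped; anchored strings shorter than 3 residues (no
    interior) are rejected.
    """
    if not cdr3:
        raise ValueError("empty CDR3")
    if convention == "core":
        return cdr3
    if convention != "anchored":
        raise ValueError(f"convention must be 'anchored' or 'core', got {convention!r}")
    if len(cdr3) < 3:
        raise ValueError(f"anchored CDR3 {cdr3!r} has no interior residues")
    if not (cdr3.startswith("C") and cdr3.endswith("W")):
        raise ValueError(f"anchored CDR3 {cdr3!r} must start with C and end with W")
    return cdr3[1:-1]


@dataclass
class HarmonizeResult:
    """A harmonized table plus the ids whose CDR3 violated the declared convention."""

    table: pd.DataFrame
    flagged: list[str] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def _canonical_call(call: str, synonyms: SynonymMap | None, granularity: str) -> str:
    if granularity == "gene":
        name = strip_allele(call)
        return synonyms.canonical(name) if synonyms else name
    if synonyms is None:
        return call
    if synonyms.level == "allele":
        return synonyms.canonical(call)
    # gene-level map on an allele-granular call: canonicalize the gene part
    # and keep the allele suffix
    gene = strip_allele(call)
    canon = synonyms.canonical(gene)
    return call if canon == gene else call.replace(gene, canon, 1)


def harmonize(
    records: pd.DataFrame,
    cdr3_convention: str = "core",
    synonyms: SynonymMap | None = None,
    granularity: str = "allele",
) -> HarmonizeResult:
    """Harmonize one tool's rearrangement table to the common schema.

    Every ``cdr3_aa`` is brought to the core convention (anchored inputs
    stripped of their first C and last W); all V/D/J calls are
    canonicalized through the synonym map and, at gene granularity, their
    allele suffixes dropped.  Record order is preserved.  Anchored records
    whose CDR3 does not carry the C/W anchors are left unchanged and
    reported in ``flagged``.  The operation is idempotent: harmonizing a
    core-convention output again changes nothing.
    """
    if granularity not in ("gene", "allele"):
        raise ValueError("granularity must be 'gene' or 'allele'")
    out = records.copy()
    flagged: list[str] = []
    if cdr3_convention == "anchored" and "cdr3_aa" in out.columns:
        normalized = []
        for sid, cdr3 in zip(out.get("sequence_id", out.index), out["cdr3_aa"]):
            text = "" if pd.isna(cdr3) else str(cdr3)
            if not text:
                normalized.append(text)
                continue
            try:
                normalized.append(normalize_cdr3(text, "anchored"))
            except ValueError:
                flagged.append(str(sid))
                normalized.append(text)
        out["cdr3_aa"] = normalized
    for col in ("v_call", "d_call", "j_call"):
        if col not in out.columns:
            continue
        out[col] = [
            ",".join(_canonical_call(c, synonyms, granularity)
                     for c in split_calls(v))
            for v in out[col]
        ]
    return HarmonizeResult(table=out, flagged=flagged)


@dataclass
class FilterReport:
    """Per-rule removal accounting for one preprocessing run."""

    input_count: int
    removed_per_rule: dict[str, int]
    output_count: int
    unique_cdr3_count: int

    @property
    def total_removed(self) -> int:
        return sum(self.removed_per_rule.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_per_rule": dict(self.removed_per_rule),
            "output_count": self.output_count,
            "unique_cdr3_count": self.unique_cdr3_count,
        }


def _primary(call) -> str | None:
    calls = split_calls(call)
    return calls[0] if calls else None


def preprocess_filter(
    records: pd.DataFrame,
    orphon_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the preprocessing filter cascade, reducing to unique CDR3s.

    Rules, in order: non-IgH locus; stop codon; out-of-frame; unproductive
    flag; orphon-gene primary call; absent or ≤4-aa CDR3; singleton CDR3
    (appearing exactly once among the survivors of the earlier rules); and
    deduplication to unique ``cdr3_aa`` (first occurrence retained).
    Records must already be harmonized to the core CDR3 convention.
    Returns the filtered table and a :class:`FilterReport`; input count
    always equals output count plus the per-rule removals.
    """
    orphons = {strip_allele(g) for g in orphon_genes}
    table = records.copy()
    input_count = len(table)
    removed = {rule: 0 for rule in FILTER_RULES}

    def _col(name, default):
        if name in table.columns:
            return table[name]
        return pd.Series([default] * len(table), index=table.index)

    def _drop(rule: str, mask: pd.Series) -> None:
        nonlocal table
        mask = mask.fillna(False).astype(bool)
        removed[rule] = int(mask.sum())
        table = table[~mask]

    if len(table):
        locus = _col("locus", "IGH").fillna("IGH")
        _drop("non_igh", locus != "IGH")
    if len(table):
        _drop("stop_codon", _col("stop_codon", False) == True)  # noqa: E712
    if len(table):
        _drop("out_of_frame", _col("vj_in_frame", True) == False)  # noqa: E712
    if len(table):
        # remaining reads are stop-free and in-frame, so "unproductive" is
        # the tool's own flag; tools without one pass (derived productive)
        _drop("unproductive", _col("productive", True) == False)  # noqa: E712
    if len(table) and orphons:
        def _is_orphon_row(row) -> bool:
            for col in ("v_call", "d_call", "j_call"):
                p = _primary(row.get(col)) if hasattr(row, "get") else None
                if p is not None and strip_allele(p) in orphons:
                    return True
            return False
        mask = table.apply(_is_orphon_row, axis=1)
        _drop("orphon", mask)
    if len(table):
        cdr3 = _col("cdr3_aa", "").fillna("").astype(str)
        _drop("cdr3_length", cdr3.str.len() <= 4)
    if len(table):
        # abundance-aware singleton rule: each record contributes its
        # duplicate_count (default 1), so a deduplicated table whose
        # aggregated counts are >= 2 passes unchanged (idempotence)
        weights = pd.to_numeric(_col("duplicate_count", 1), errors="coerce").fillna(1)
        abundance = weights.groupby(table["cdr3_aa"]).transform("sum")
        _drop("singleton", abundance == 1)
    if len(table):
        weights = pd.to_numeric(_col("duplicate_count", 1), errors="coerce").fillna(1)
        totals = weights.groupby(table["cdr3_aa"]).sum()
        dup_mask = table["cdr3_aa"].duplicated(keep="first")
        _drop("duplicate", dup_mask)
        if len(table):
            table = table.copy()
            table["duplicate_count"] = (
                table["cdr3_aa"].map(totals).astype("Int64")
            )

    report = FilterReport(
        input_count=input_count,
        removed_per_rule=removed,
        output_count=len(table),
        unique_cdr3_count=int(table["cdr3_aa"].nunique()) if len(table) else 0,
    )
    return table, report


def alignment_counts(
    before: pd.DataFrame,
    after: pd.DataFrame,
    gene_type: str = "V",
) -> pd.DataFrame:
    """Per-gene annotation counts before vs after preprocessing.

    Counts use the primary call of the requested gene type.  Returns one
    row per gene with ``annotated_count``, ``retained_count`` and
    ``lost_fraction`` (1 − retained/annotated), plus a pooled ``overall``
    row; genes with zero annotated records are omitted.  ``after`` must be
    a subset of ``before`` by sequence id.
    """
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[gene_type]
    before_ids = set(before["sequence_id"])
    extra = set(after["sequence_id"]) - before_ids
    if extra:
        raise DataError(
            f"after-table ids absent from before-table: {sorted(extra)[:5]}"
        )

    def _gene_counts(table: pd.DataFrame) -> pd.Series:
        genes = table[col].map(_primary).dropna().map(strip_allele)
        return genes.value_counts()

    annotated = _gene_counts(before)
    retained = _gene_counts(after).reindex(annotated.index, fill_value=0)
    out = pd.DataFrame({
        "gene": annotated.index,
        "annotated_count": annotated.values,
        "retained_count": retained.values,
    })
    out = out[out["annotated_count"] > 0]
    out["lost_fraction"] = 1.0 - out["retained_count"] / out["annotated_count"]
    total_ann = int(out["annotated_count"].sum())
    total_ret = int(out["retained_count"].sum())
    overall = pd.DataFrame([{
        "gene": "overall",
        "annotated_count": total_ann,
        "retained_count": total_ret,
        "lost_fraction": (1.0 - total_ret / total_ann) if total_ann else 0.0,
    }])
    out = pd.concat([out.sort_values("gene").reset_index(drop=True), overall],
                    ignore_index=True)
    return out
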