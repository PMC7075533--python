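"""File formats: IMGT-style germline FASTA, AIRR Rearrangement TSV, change-log TSV.

Germline FASTA headers follow the pipe-delimited IMGT GENE-DB dialect::

    >accession|allele_name|species|functionality

AIRR Rearrangement tables are TSV with boolean columns encoded as T/F.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    ChangeEvent,
    ChangeLog,
    GermlineAllele,
    GroundTruthRearrangement,
    ReferenceSet,
)

logger = logging.getLogger(__name__)

#: Canonical column order of the harmonized rearrangement schema.
AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction_aa",
    "cdr3_aa",
    "productive",
    "stop_codon",
    "vj_in_frame",
    "locus",
    "duplicate_count",
]

_BOOL_COLUMNS = ("productive", "stop_codon", "vj_in_frame")

_GENE_TYPE_PREFIX = {"IGHV": "V", "IGHD": "D", "IGHJ": "J"}


class FastaHeaderError(ValueError):
    """A germline FASTA record whose header does not follow the dialect."""


def _gene_type_from_name(allele_name: str) -> str:
    for prefix, gt in _GENE_TYPE_PREFIX.items():
        if allele_name.startswith(prefix):
            return gt
    raise FastaHeaderError(
        f"cannot infer gene type (IGHV/IGHD/IGHJ prefix) from {allele_name!r}"
    )


def read_reference_fasta(path: str | Path, label: str | None = None) -> ReferenceSet:
    """Read a germline reference set from pipe-delimited IMGT-style FASTA.

    One :class:`GermlineAllele` per record; allele names are parsed into the
    subgroup/gene/allele hierarchy and the orphon flag is set from IMGT
    orphon nomenclature ("/OR" infix or trailing "D").  An empty file yields
    an empty set with a logged warning.  A malformed header raises
    :class:`FastaHeaderError` naming the offending record.
    """
    path = Path(path)
    alleles: list[GermlineAllele] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) < 4:
            raise FastaHeaderError(
                f"record {rec.id!r} in {path.name}: expected "
                f">accession|allele_name|species|functionality, got {rec.description!r}"
            )
        allele_name = fields[1].strip()
        functionality = fields[3].strip() or "F"
        try:
            allele = GermlineAllele.from_name(
                allele_name,
                gene_type=_gene_type_from_name(allele_name),
                nt_sequence=str(rec.seq).upper(),
                functionality=functionality,
            )
        except ValueError as exc:
            raise FastaHeaderError(f"record {rec.id!r} in {path.name}: {exc}") from exc
        alleles.append(allele)
    if not alleles:
        logger.warning("reference FASTA %s contained no records", path)
    return ReferenceSet(label=label or path.stem, alleles=alleles)


def write_reference_fasta(reference: ReferenceSet, path: str | Path) -> None:
    """Serialize a reference set in the pipe-delimited header dialect."""
    records = []
    for i, a in enumerate(reference.alleles, start=1):
        header = f"X{i:05d}|{a.allele_name}|Homo sapiens|{a.functionality}"
        records.append(SeqRecord(Seq(a.nt_sequence), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def _encode_bool(v) -> str:
    if pd.isna(v):
        return ""
    return "T" if bool(v) else "F"


def _decode_bool(v):
    if isinstance(v, bool):
        return v
    if pd.isna(v) or v == "":
        return pd.NA
    s = str(v).strip().upper()
    if s in ("T", "TRUE", "1"):
        return True
    if s in ("F", "FALSE", "0"):
        return False
    raise ValueError(f"cannot decode AIRR boolean {v!r}")


def write_rearrangement_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rearrangement table as AIRR TSV (booleans as T/F)."""
    out = table.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(_encode_bool)
    cols = [c for c in AIRR_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep="\t", index=False)


def read_rearrangement_tsv(path: str | Path) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV; T/F columns become nullable booleans."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _BOOL_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map(_decode_bool).astype("boolean")
    if "duplicate_count" in table.columns:
        table["duplicate_count"] = pd.to_numeric(
            table["duplicate_count"], errors="coerce"
        ).astype("Int64")
    return table


def truth_to_table(truth: Iterable[GroundTruthRearrangement]) -> pd.DataFrame:
    """Express ground-truth rearrangements in the AIRR schema (gene-level calls)."""
    rows = []
    for t in truth:
        rows.append(
            {
                "sequence_id": t.sequence_id,
                "v_call": t.true_v_gene,
                "d_call": t.true_d_gene,
                "j_call": t.true_j_gene,
                "junction_aa": t.junction_aa,
                "cdr3_aa": t.cdr3_aa,
                "productive": t.productive,
                "stop_codon": "*" in t.junction_aa,
                "vj_in_frame": True,
                "locus": "IGH",
                "duplicate_count": 1,
            }
        )
    table = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    for col in _BOOL_COLUMNS:
        table[col] = table[col].astype("boolean")
    return table


def read_change_log_tsv(path: str | Path) -> ChangeLog:
    """Read a change log TSV with columns release_date (ISO 8601), change_type, target."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"release_date", "change_type", "target"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"change log {path} missing columns: {sorted(missing)}")
    events = [
        ChangeEvent(
            release_date=_dt.date.fromisoformat(row.release_date),
            change_type=row.change_type,
            target=row.target,
        )
        for row in table.itertuples()
    ]
    return ChangeLog(events=events)


def write_change_log_tsv(log: ChangeLog, path: str | Path) -> None:
    rows = [
        {
            "release_date": e.release_date.isoformat(),
            "change_type": e.change_type,
            "target": e.target,
        }
        for e in log.events
    ]
    pd.DataFrame(rows, columns=["release_date", "change_type", "target"]).to_csv(
        path, sep="\t", index=False
    )
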