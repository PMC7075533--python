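"""Shared domain types for repertoire annotation benchmarking.

The central objects are germline reference sets (V/D/J gene segments with a
subgroup > gene > allele naming hierarchy, IMGT-style), simulated
ground-truth rearrangements, emulated annotator error profiles, and germline
change logs.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

__all__ = [
    "GermlineAllele",
    "ReferenceSet",
    "SimulationConfig",
    "GroundTruthRearrangement",
    "AnnotatorProfile",
    "ChangeEvent",
    "ChangeLog",
    "CHANGE_TYPES",
    "parse_allele_name",
    "strip_allele",
]

#: The five categories of germline reference change tracked across releases.
CHANGE_TYPES = (
    "gene_removal",
    "gene_addition",
    "allele_addition",
    "sequence_change",
    "metadata_change",
)

_ALLELE_RE = re.compile(r"^(?P<gene>[A-Z0-9/\-]+)\*(?P<allele>\d{2})$")
_SUBGROUP_RE = re.compile(r"^(?P<subgroup>IG[HKL][VDJ]\d+|IG[HKL][VDJ])")
_DNA_RE = re.compile(r"^[ACGT]+$")


def parse_allele_name(allele_name: str) -> tuple[str, str, str]:
    """Split an allele name like ``IGHV1-18*01`` into (subgroup, gene, allele).

    Returns ``("IGHV1", "IGHV1-18", "IGHV1-18*01")``.  Raises ``ValueError``
    for names without a ``gene*NN`` structure.
    """
    m = _ALLELE_RE.match(allele_name)
    if not m:
        raise ValueError(f"not a valid allele name: {allele_name!r}")
    gene = m.group("gene")
    sg = _SUBGROUP_RE.match(gene)
    if not sg:
        raise ValueError(f"cannot extract subgroup from gene name: {gene!r}")
    return sg.group("subgroup"), gene, allele_name


def strip_allele(name: str) -> str:
    """Drop the ``*NN`` allele suffix, if present: ``IGHV1-18*01 -> IGHV1-18``."""
    return name.split("*", 1)[0]


def split_calls(call: object) -> list[str]:
    """Split an AIRR call string ("IGHV1-18*01,IGHV1-2*02") into a list.

    Empty strings, None and NaN yield an empty list (no hit).
    """
    if call is None:
        return []
    try:
        if call != call:  # NaN-like scalars (float nan, pandas NA)
            return []
    except TypeError:
        return []
    text = str(call).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(",") if part.strip()]


def _is_orphon(gene_name: str) -> bool:
    # IMGT orphon nomenclature: "/OR" infix (e.g. IGHV1/OR15-1) or a trailing
    # "D" duplicate-locus marker (e.g. IGHV1-69D).
    return "/OR" in gene_name or gene_name.split("*", 1)[0].endswith("D")


@dataclass(frozen=True)
class GermlineAllele:
    """One germline allele: a named V, D or J segment nucleotide sequence."""

    allele_name: str
    gene_name: str
    subgroup_name: str
    gene_type: str  # "V", "D" or "J"
    nt_sequence: str
    functionality: str = "F"  # F / ORF / P
    orphon: bool = False

    def __post_init__(self) -> None:
        if self.gene_type not in ("V", "D", "J"):
            raise ValueError(f"gene_type must be V, D or J, got {self.gene_type!r}")
        if not self.nt_sequence or not _DNA_RE.match(self.nt_sequence):
            raise ValueError(f"nt_sequence must be non-empty DNA for {self.allele_name}")
        if not self.gene_name.startswith(self.subgroup_name):
            raise ValueError(
                f"gene {self.gene_name!r} does not start with subgroup {self.subgroup_name!r}"
            )
        if not self.allele_name.startswith(self.gene_name + "*"):
            raise ValueError(
                f"allele {self.allele_name!r} does not extend gene {self.gene_name!r}"
            )
        if self.functionality not in ("F", "ORF", "P"):
            raise ValueError(f"functionality must be F/ORF/P, got {self.functionality!r}")

    @classmethod
    def from_name(
        cls,
        allele_name: str,
        gene_type: str,
        nt_sequence: str,
        functionality: str = "F",
    ) -> "GermlineAllele":
        subgroup, gene, allele = parse_allele_name(allele_name)
        return cls(
            allele_name=allele,
            gene_name=gene,
            subgroup_name=subgroup,
            gene_type=gene_type,
            nt_sequence=nt_sequence,
            functionality=functionality,
            orphon=_is_orphon(gene),
        )


@dataclass
class ReferenceSet:
    """A labelled, optionally dated collection of germline alleles."""

    label: str
    alleles: list[GermlineAllele] = field(default_factory=list)
    release_date: _dt.date | None = None

    def __post_init__(self) -> None:
        names = [a.allele_name for a in self.alleles]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate allele names in reference set: {dupes}")

    def of_type(self, gene_type: str) -> list[GermlineAllele]:
        return [a for a in self.alleles if a.gene_type == gene_type]

    def gene_names(self, gene_type: str | None = None) -> list[str]:
        """Distinct gene names, in first-seen order."""
        seen: dict[str, None] = {}
        for a in self.alleles:
            if gene_type is None or a.gene_type == gene_type:
                seen.setdefault(a.gene_name, None)
        return list(seen)

    def names_at_level(self, level: str, gene_type: str | None = None) -> set[str]:
        """Distinct identifiers at a naming level.

        ``level`` is one of subgroup / gene / allele / nt_sequence; at the
        nt_sequence level items are compared as identical strings.
        """
        sel = (a for a in self.alleles if gene_type is None or a.gene_type == gene_type)
        if level == "subgroup":
            return {a.subgroup_name for a in sel}
        if level == "gene":
            return {a.gene_name for a in sel}
        if level == "allele":
            return {a.allele_name for a in sel}
        if level == "nt_sequence":
            return {a.nt_sequence for a in sel}
        raise ValueError(f"unknown naming level: {level!r}")

    def allele(self, allele_name: str) -> GermlineAllele:
        for a in self.alleles:
            if a.allele_name == allele_name:
                return a
        raise KeyError(allele_name)

    def has_gene(self, gene_name: str, gene_type: str | None = None) -> bool:
        return any(
            a.gene_name == gene_name
            for a in self.alleles
            if gene_type is None or a.gene_type == gene_type
        )

    def relabel(self, label: str) -> "ReferenceSet":
        return ReferenceSet(label=label, alleles=list(self.alleles), release_date=self.release_date)


# Preset clonal compositions: ratio of mutated to base sequences.
COMPOSITION_RATIOS = {"diverse": 2, "polarized": 5}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for a simulated heavy-chain repertoire.

    ``n_base`` naive founder sequences receive ``n_mutated`` somatically
    hypermutated descendants.  The ``diverse`` composition spreads mutants
    uniformly over founders (many small clonal clusters); ``polarized``
    concentrates them on few founders (large expanded clusters).
    ``mutation_rate`` is the expected number of nucleotide substitutions a
    descendant acquires relative to its parent sequence.
    """

    n_base: int
    n_mutated: int
    composition_label: str = "diverse"
    mutation_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        if self.n_mutated < 0:
            raise ValueError("n_mutated must be >= 0")
        if self.composition_label not in COMPOSITION_RATIOS:
            raise ValueError(
                f"composition_label must be one of {sorted(COMPOSITION_RATIOS)}"
            )
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")

    @classmethod
    def diverse(cls, n_base: int = 100_000, seed: int = 0, **kw) -> "SimulationConfig":
        """Diverse preset: mutated/base ratio 2 (100k base / 200k mutated at full scale)."""
        return cls(n_base=n_base, n_mutated=2 * n_base, composition_label="diverse",
                   seed=seed, **kw)

    @classmethod
    def polarized(cls, n_base: int = 20_000, seed: int = 0, **kw) -> "SimulationConfig":
        """Polarized preset: mutated/base ratio 5 (20k base / 100k mutated at full scale)."""
        return cls(n_base=n_base, n_mutated=5 * n_base, composition_label="polarized",
                   seed=seed, **kw)


@dataclass
class GroundTruthRearrangement:
    """A simulated read with its known originating germline genes and CDR3."""

    sequence_id: str
    true_v_gene: str
    true_d_gene: str
    true_j_gene: str
    nt_sequence: str
    junction_aa: str
    cdr3_aa: str
    productive: bool
    lineage_id: str
    # nt span [start, end) of the junction within nt_sequence; internal,
    # used by the mutation model to re-derive the CDR3.
    junction_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.junction_aa[1:-1] != self.cdr3_aa:
            raise ValueError("cdr3_aa must equal junction_aa without its anchors")
        if not (self.junction_aa.startswith("C") and self.junction_aa.endswith("W")):
            raise ValueError("junction_aa must begin with C and end with W")
        if self.productive and "*" in self.junction_aa:
            raise ValueError("productive rearrangement cannot contain a stop codon")


@dataclass(frozen=True)
class AnnotatorProfile:
    """Error model for an emulated annotation tool.

    ``mishit_rate_*`` are per-read probabilities that the assigned gene of
    that type differs from the true one (redrawn uniformly from the other
    genes of the type).  ``confusion_pairs`` overrides the uniform redraw for
    specific true genes with a targeted wrong assignment, emulating
    systematic confusions between near-identical germlines.  ``granularity``
    controls whether calls carry allele suffixes; ``cdr3_convention``
    controls whether the reported CDR3 keeps its conserved anchors
    (``anchored``: C...W junction) or not (``core``).
    """

    tool_label: str
    mishit_rate_v: float = 0.0
    mishit_rate_d: float = 0.0
    mishit_rate_j: float = 0.0
    confusion_pairs: dict[str, tuple[str, float]] = field(default_factory=dict)
    granularity: str = "allele"  # "gene" or "allele"
    cdr3_convention: str = "core"  # "anchored" or "core"
    drop_rate: float = 0.0
    unproductive_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mishit_rate_v", "mishit_rate_d", "mishit_rate_j",
                     "drop_rate", "unproductive_flip_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for true_gene, (assigned, p) in self.confusion_pairs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"confusion probability for {true_gene}->{assigned} outside [0, 1]"
                )
        if self.granularity not in ("gene", "allele"):
            raise ValueError("granularity must be 'gene' or 'allele'")
        if self.cdr3_convention not in ("anchored", "core"):
            raise ValueError("cdr3_convention must be 'anchored' or 'core'")


@dataclass(frozen=True, order=True)
class ChangeEvent:
    """One dated change to a germline reference release."""

    release_date: _dt.date
    change_type: str
    target: str

    def __post_init__(self) -> None:
        if self.change_type not in CHANGE_TYPES:
            raise ValueError(
                f"change_type must be one of {CHANGE_TYPES}, got {self.change_type!r}"
            )


@dataclass
class ChangeLog:
    """Germline change events, ordered by release date.

    ``releases`` may list release dates explicitly, so a release that
    introduced no change still counts toward update-interval statistics;
    when omitted, release dates are derived from the events.
    """

    events: list[ChangeEvent] = field(default_factory=list)
    releases: list[_dt.date] | None = None

    def __post_init__(self) -> None:
        dates = [e.release_date for e in self.events]
        if dates != sorted(dates):
            self.events = sorted(self.events, key=lambda e: e.release_date)
        if self.releases is not None:
            self.releases = sorted(set(self.releases))
            missing = {e.release_date for e in self.events} - set(self.releases)
            if missing:
                raise ValueError(f"events dated outside listed releases: {sorted(missing)}")

    @property
    def release_dates(self) -> list[_dt.date]:
        """Distinct release dates, ascending."""
        if self.releases is not None:
            return list(self.releases)
        return sorted({e.release_date for e in self.events})

    def window(self, from_date: _dt.date | None = None,
               to_date: _dt.date | None = None) -> "ChangeLog":
        """Events with release_date in the inclusive [from_date, to_date] window."""
        if from_date is not None and to_date is not None and from_date > to_date:
            raise ValueError("from_date must be <= to_date")
        ev = [
            e for e in self.events
            if (from_date is None or e.release_date >= from_date)
            and (to_date is None or e.release_date <= to_date)
        ]
        return ChangeLog(events=ev)
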