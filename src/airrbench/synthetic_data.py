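"""Synthetic germlines, repertoires, annotator outputs and change logs.

Everything downstream of real sequencing data is emulated here with known
ground truth:

* :func:`generate_reference_set` builds a germline V/D/J reference with an
  IMGT-like naming hierarchy, 1-3 alleles per gene, and optional synonym
  pairs (distinct gene names carrying identical nucleotide sequences).
* :func:`generate_repertoire` simulates a heavy-chain repertoire as clonal
  lineages: base (naive) V(D)J rearrangements plus somatically hypermutated
  descendants, in a ``diverse`` (many small clusters) or ``polarized``
  (few expanded clusters) composition.
* :func:`emulate_annotator` derives one tool's annotation table from ground
  truth under a configurable error profile (gene mishits, targeted
  confusions, naming granularity, CDR3 boundary convention, dropped reads).
* :func:`generate_change_log` produces dated germline change events of the
  five tracked categories.

The mutation model uses nucleotide substitutions only (no indels), applied
along a random recursive lineage tree, with a configurable fraction of
substitutions targeted at the junction. Substitution-dominated, CDR-biased
hypermutation keeps mutated CDR3s within small edit distance of their
clonal founder, which is what gives expanded clones their characteristic
dense similarity-network neighbourhoods.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .models import (
    CHANGE_TYPES,
    AnnotatorProfile,
    ChangeEvent,
    ChangeLog,
    GermlineAllele,
    GroundTruthRearrangement,
    ReferenceSet,
    SimulationConfig,
)
from . import airr_io

__all__ = [
    "generate_reference_set",
    "generate_repertoire",
    "emulate_annotator",
    "generate_change_log",
    "ConfigurationError",
    "DataError",
]

_NT = np.array(list("ACGT"))

#: Fraction of substitutions targeted at the junction (CDR3 hot spot).
JUNCTION_BIAS = 0.25

#: Exponent of the power-law allocation of mutants over bases in the
#: polarized composition (larger -> more extreme clonal expansion).
POLARIZED_EXPONENT = 1.5


class ConfigurationError(ValueError):
    """A simulation request inconsistent with the supplied reference."""


class DataError(ValueError):
    """Input records referencing unknown genes or ids."""


def _random_nt(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _substituted(rng: np.random.Generator, seq: str, pos: int) -> str:
    old = seq[pos]
    choices = [c for c in "ACGT" if c != old]
    return seq[:pos] + choices[rng.integers(0, 3)] + seq[pos + 1:]


# ---------------------------------------------------------------------------
# Reference set generation
# ---------------------------------------------------------------------------

def generate_reference_set(
    n_v: int,
    n_d: int,
    n_j: int,
    n_synonyms: int = 0,
    seed: int = 0,
) -> ReferenceSet:
    """Generate a synthetic germline reference set.

    Creates ``n_v`` V, ``n_d`` D and ``n_j`` J gene names, each with 1-3
    alleles. V sequences end in a conserved TGT codon (the junction
    cysteine) and J sequences begin with a conserved TGG codon (the
    junction tryptophan), so junction extraction is well defined.  Exactly
    ``n_synonyms`` disjoint pairs of distinct V gene names share an
    identical nucleotide sequence, emulating duplicate germlines published
    under different names.  Deterministic given ``seed``.
    """
    for name, val in (("n_v", n_v), ("n_d", n_d), ("n_j", n_j),
                      ("n_synonyms", n_synonyms)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    if n_v < 1 or n_d < 1 or n_j < 1:
        raise ValueError(
            "a reference set needs at least one V, one D and one J gene "
            "for repertoire simulation"
        )
    if 2 * n_synonyms > n_v:
        raise ValueError(
            f"cannot build {n_synonyms} disjoint synonym pairs from {n_v} V genes"
        )
    rng = np.random.default_rng(seed)
    alleles: list[GermlineAllele] = []

    def _make_gene(gene_name: str, gene_type: str, base_seq: str,
                   protect_head: int, protect_tail: int) -> list[GermlineAllele]:
        n_alleles = int(rng.integers(1, 4))
        out = []
        seq = base_seq
        for k in range(1, n_alleles + 1):
            if k > 1:
                # alleles differ by 1-2 substitutions away from the anchors
                for _ in range(int(rng.integers(1, 3))):
                    pos = int(rng.integers(protect_head, len(seq) - protect_tail))
                    seq = _substituted(rng, seq, pos)
            out.append(GermlineAllele.from_name(
                f"{gene_name}*{k:02d}", gene_type, seq))
        return out

    v_genes = [f"IGHV{(i % 7) + 1}-{i + 1}" for i in range(n_v)]
    for gene in v_genes:
        base = _random_nt(rng, 87) + "TGT"  # conserved 3' Cys codon
        alleles.extend(_make_gene(gene, "V", base, 0, 3))
    for i in range(n_d):
        gene = f"IGHD{(i % 7) + 1}-{i + 1}"
        length = int(rng.integers(12, 28))
        alleles.extend(_make_gene(gene, "D", _random_nt(rng, length), 0, 0))
    for i in range(n_j):
        gene = f"IGHJ{i + 1}"
        base = "TGG" + _random_nt(rng, 21)  # conserved 5' Trp codon
        alleles.extend(_make_gene(gene, "J", base, 3, 0))

    if n_synonyms:
        by_name = {a.allele_name: a for a in alleles}
        out = []
        synonym_targets = {}
        for i in range(n_synonyms):
            source = v_genes[i]
            target = v_genes[n_v - 1 - i]
            synonym_targets[target] = by_name[f"{source}*01"].nt_sequence
        for a in alleles:
            if a.gene_name in synonym_targets:
                if a.allele_name.endswith("*01"):
                    out.append(GermlineAllele.from_name(
                        a.allele_name, a.gene_type, synonym_targets[a.gene_name]))
                # drop extra alleles of the synonym target so the pair is exact
            else:
                out.append(a)
        alleles = out

    return ReferenceSet(label=f"synthetic-{seed}", alleles=alleles)


# ---------------------------------------------------------------------------
# Repertoire simulation
# ---------------------------------------------------------------------------

def _pick_allele(rng: np.random.Generator, reference: ReferenceSet,
                 gene_type: str) -> GermlineAllele:
    genes = reference.gene_names(gene_type)
    gene = genes[rng.integers(len(genes))]
    options = [a for a in reference.of_type(gene_type) if a.gene_name == gene]
    return options[rng.integers(len(options))]


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _simulate_base(rng: np.random.Generator, reference: ReferenceSet,
                   sequence_id: str) -> GroundTruthRearrangement:
    for _ in range(50):
        v = _pick_allele(rng, reference, "V")
        d = _pick_allele(rng, reference, "D")
        j = _pick_allele(rng, reference, "J")
        n1 = _random_nt(rng, int(rng.integers(0, 13)))
        n2_len = int(rng.integers(0, 13))
        pad = (-(len(n1) + len(d.nt_sequence) + n2_len)) % 3
        n2 = _random_nt(rng, n2_len + pad)
        seq = v.nt_sequence + n1 + d.nt_sequence + n2 + j.nt_sequence
        start = len(v.nt_sequence) - 3
        end = len(v.nt_sequence) + len(n1) + len(d.nt_sequence) + len(n2) + 3
        junction = _translate(seq[start:end])
        if "*" in junction:
            continue  # redraw N regions until the junction is open
        return GroundTruthRearrangement(
            sequence_id=sequence_id,
            true_v_gene=v.gene_name,
            true_d_gene=d.gene_name,
            true_j_gene=j.gene_name,
            nt_sequence=seq,
            junction_aa=junction,
            cdr3_aa=junction[1:-1],
            productive=True,
            lineage_id=sequence_id,
            junction_span=(start, end),
        )
    raise RuntimeError("could not draw a stop-free junction in 50 attempts")


def _mutable_positions(span: tuple[int, int], length: int) -> tuple[range, range, range]:
    start, end = span
    # anchors (first and last junction codon) are conserved
    return range(0, start), range(start + 3, end - 3), range(end, length)


def _simulate_mutant(
    rng: np.random.Generator,
    parent: GroundTruthRearrangement,
    base: GroundTruthRearrangement,
    sequence_id: str,
    mutation_rate: float,
) -> GroundTruthRearrangement:
    seq = parent.nt_sequence
    span = parent.junction_span
    assert span is not None
    left, core, right = _mutable_positions(span, len(seq))
    outside = list(left) + list(right)
    k = max(1, int(rng.poisson(mutation_rate)))
    for _ in range(k):
        if core and rng.random() < JUNCTION_BIAS:
            pos = core[rng.integers(len(core))]
        else:
            pos = outside[rng.integers(len(outside))]
        seq = _substituted(rng, seq, pos)
    if seq == base.nt_sequence:  # rare full reversion; force a framework change
        seq = _substituted(rng, seq, outside[rng.integers(len(outside))])
    junction = _translate(seq[span[0]:span[1]])
    return GroundTruthRearrangement(
        sequence_id=sequence_id,
        true_v_gene=base.true_v_gene,
        true_d_gene=base.true_d_gene,
        true_j_gene=base.true_j_gene,
        nt_sequence=seq,
        junction_aa=junction,
        cdr3_aa=junction[1:-1],
        productive="*" not in junction,
        lineage_id=base.lineage_id,
        junction_span=span,
    )


def _allocate_mutants(rng: np.random.Generator, n_base: int, n_mutated: int,
                      composition: str) -> np.ndarray:
    if composition == "diverse":
        weights = np.full(n_base, 1.0 / n_base)
    else:  # polarized: heavy-tailed power-law split over bases
        ranks = np.arange(1, n_base + 1, dtype=float)
        weights = ranks ** -POLARIZED_EXPONENT
        weights /= weights.sum()
    return rng.multinomial(n_mutated, weights)


def generate_repertoire(
    reference: ReferenceSet,
    config: SimulationConfig,
) -> list[GroundTruthRearrangement]:
    """Simulate a heavy-chain repertoire with known ground truth.

    Returns exactly ``n_base + n_mutated`` records (bases first).  Each
    mutated record derives from a base lineage: its parent is drawn
    uniformly from the lineage members generated so far (a random recursive
    tree), and it differs from its parent by at least one nucleotide
    substitution.  The ``diverse`` composition spreads mutants uniformly
    over bases; ``polarized`` concentrates them with a power-law allocation
    so large clonal clusters exist.
    """
    for gt in ("V", "D", "J"):
        if not reference.gene_names(gt):
            raise ConfigurationError(f"reference has no {gt} genes")
    rng = np.random.default_rng(config.seed)
    bases = [
        _simulate_base(rng, reference, f"S{i:07d}")
        for i in range(config.n_base)
    ]
    counts = _allocate_mutants(rng, config.n_base, config.n_mutated,
                               config.composition_label)
    mutants: list[GroundTruthRearrangement] = []
    next_id = config.n_base
    for base, m in zip(bases, counts):
        members = [base]
        for _ in range(int(m)):
            parent = members[rng.integers(len(members))]
            child = _simulate_mutant(rng, parent, base, f"S{next_id:07d}",
                                     config.mutation_rate)
            members.append(child)
            mutants.append(child)
            next_id += 1
    return bases + mutants


# ---------------------------------------------------------------------------
# Annotator emulation
# ---------------------------------------------------------------------------

def _gene_pool(reference: ReferenceSet) -> dict[str, list[str]]:
    return {gt: reference.gene_names(gt) for gt in ("V", "D", "J")}


def _assign_gene(
    rng: np.random.Generator,
    true_gene: str,
    gene_type: str,
    profile: AnnotatorProfile,
    pool: Sequence[str],
) -> str:
    if true_gene in profile.confusion_pairs:
        wrong, p = profile.confusion_pairs[true_gene]
        return wrong if rng.random() < p else true_gene
    rate = {"V": profile.mishit_rate_v, "D": profile.mishit_rate_d,
            "J": profile.mishit_rate_j}[gene_type]
    if rate > 0 and rng.random() < rate:
        others = [g for g in pool if g != true_gene]
        if others:
            return others[rng.integers(len(others))]
    return true_gene


def emulate_annotator(
    truth: Iterable[GroundTruthRearrangement],
    profile: AnnotatorProfile,
    reference: ReferenceSet,
):
    """Derive one emulated tool's AIRR rearrangement table from ground truth.

    For each non-dropped read, the assigned gene of each type equals the
    true gene except with probability ``mishit_rate`` (uniform redraw among
    the other genes of that type) or per a configured confusion pair.
    ``granularity='allele'`` decorates calls with an allele suffix drawn
    from the reference; ``'gene'`` reports bare gene names.  The CDR3
    column follows the profile's boundary convention.  Deterministic given
    ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    pool = _gene_pool(reference)
    allele_index: dict[str, list[str]] = {}
    for a in reference.alleles:
        allele_index.setdefault(a.gene_name, []).append(a.allele_name)

    rows = []
    for t in truth:
        for gene, gt in ((t.true_v_gene, "V"), (t.true_d_gene, "D"),
                         (t.true_j_gene, "J")):
            if gene not in allele_index:
                raise DataError(
                    f"read {t.sequence_id}: true {gt} gene {gene!r} not in reference "
                    f"{reference.label!r}"
                )
        if profile.drop_rate > 0 and rng.random() < profile.drop_rate:
            continue
        calls = {}
        for col, gene, gt in (("v_call", t.true_v_gene, "V"),
                              ("d_call", t.true_d_gene, "D"),
                              ("j_call", t.true_j_gene, "J")):
            assigned = _assign_gene(rng, gene, gt, profile, pool[gt])
            if profile.granularity == "allele":
                options = allele_index.get(assigned, [assigned + "*01"])
                assigned = options[rng.integers(len(options))]
            calls[col] = assigned
        productive = t.productive
        if profile.unproductive_flip_rate > 0 and rng.random() < profile.unproductive_flip_rate:
            productive = not productive
        if profile.cdr3_convention == "anchored":
            cdr3 = t.junction_aa
        else:
            cdr3 = t.cdr3_aa
        rows.append({
            "sequence_id": t.sequence_id,
            **calls,
            "junction_aa": t.junction_aa,
            "cdr3_aa": cdr3,
            "productive": productive,
            "stop_codon": "*" in t.junction_aa,
            "vj_in_frame": True,
            "locus": "IGH",
            "duplicate_count": 1,
        })
    import pandas as pd

    table = pd.DataFrame(rows, columns=airr_io.AIRR_COLUMNS)
    for col in ("productive", "stop_codon", "vj_in_frame"):
        table[col] = table[col].astype("boolean")
    return table


# ---------------------------------------------------------------------------
# Change-log generation
# ---------------------------------------------------------------------------

def generate_change_log(
    n_releases: int,
    rates: Mapping[str, float],
    start_date: _dt.date = _dt.date(2010, 7, 28),
    interval_weeks: float = 13.0,
    seed: int = 0,
    exact_totals: bool = False,
) -> ChangeLog:
    """Generate a dated germline change log over ``n_releases`` releases.

    ``rates`` maps change types to expected event counts per release
    (Poisson-distributed); with ``exact_totals=True`` each rate is instead
    an exact overall count, distributed multinomially over the releases.
    Releases are ``interval_weeks`` apart starting at ``start_date``.
    """
    if n_releases < 1:
        raise ValueError("n_releases must be >= 1")
    unknown = set(rates) - set(CHANGE_TYPES)
    if unknown:
        raise ValueError(f"unknown change types: {sorted(unknown)}")
    if any(v < 0 for v in rates.values()):
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    dates = [start_date + _dt.timedelta(days=round(i * interval_weeks * 7))
             for i in range(n_releases)]
    events: list[ChangeEvent] = []
    counter = 0
    for ctype in CHANGE_TYPES:
        rate = float(rates.get(ctype, 0.0))
        if rate == 0:
            continue
        if exact_totals:
            per_release = rng.multinomial(int(round(rate)),
                                          np.full(n_releases, 1.0 / n_releases))
        else:
            per_release = rng.poisson(rate, size=n_releases)
        for date, n in zip(dates, per_release):
            for _ in range(int(n)):
                counter += 1
                events.append(ChangeEvent(
                    release_date=date,
                    change_type=ctype,
                    target=f"IGHV{(counter % 7) + 1}-{counter}",
                ))
    return ChangeLog(events=events, releases=dates)
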