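"""Germline reference set comparison and change-history tabulation.

Reference sets are compared at four naming levels — subgroup (IGHV1), gene
(IGHV1-18), allele (IGHV1-18*01) and raw nucleotide sequence — by exact
string identity, yielding the counts of items exclusive to every subset of
the compared sets. Change logs are summarized per change type and per
release, with update-interval statistics in weeks.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .airr_io import read_reference_fasta  # noqa: F401  (module-level I/O entry point)
from .models import CHANGE_TYPES, ChangeLog, ReferenceSet, strip_allele

__all__ = [
    "MembershipTable",
    "ChangeSummary",
    "IntervalStats",
    "SynonymMap",
    "read_reference_fasta",
    "intersect_references",
    "tabulate_changes",
    "update_interval_stats",
    "build_synonym_map",
]

NAMING_LEVELS = ("subgroup", "gene", "allele", "nt_sequence")


@dataclass
class MembershipTable:
    """Exclusive-region counts for a multi-set comparison at one naming level.

    ``region_counts`` maps each non-empty subset of set labels to the number
    of items found in exactly those sets and no others (the regions of a
    Venn/UpSet decomposition).
    """

    level: str
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
        """Items present in every compared set."""
        return self.region_counts.get(frozenset(self.totals), 0)

    @property
    def shared_percentage(self) -> int:
        """Shared-by-all items as integer percent of the union."""
        union = self.union_size
        if union == 0:
            return 0
        return round(100.0 * self.shared_by_all / union)

    def exclusive(self, label: str) -> int:
        """Items found only in ``label``."""
        return self.region_counts.get(frozenset([label]), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "+".join(sorted(region)), "count": count}
            for region, count in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "count"])


def intersect_references(
    sets: Sequence[ReferenceSet],
    level: str = "gene",
    gene_type_filter: str | None = None,
) -> MembershipTable:
    """Partition items of ≥2 reference sets into exclusive membership regions.

    Items are compared as exact strings at the chosen naming level,
    optionally restricted to one gene type.  The nt_sequence level compares
    sequences as identical strings.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 reference sets to intersect")
    if level not in NAMING_LEVELS:
        raise ValueError(f"level must be one of {NAMING_LEVELS}, got {level!r}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"reference set labels must be distinct: {labels}")
    items = {s.label: s.names_at_level(level, gene_type_filter) for s in sets}
    totals = {lab: len(v) for lab, v in items.items()}
    union = set().union(*items.values())
    region_counts: dict[frozenset[str], int] = {}
    for item in union:
        region = frozenset(lab for lab in labels if item in items[lab])
        region_counts[region] = region_counts.get(region, 0) + 1
    return MembershipTable(level=level, totals=totals, region_counts=region_counts)


@dataclass
class ChangeSummary:
    """Per-type change counts over a date window, with per-release increments."""

    per_type: dict[str, int]
    per_release: pd.DataFrame  # columns: release_date + one per change type

    @property
    def total(self) -> int:
        return sum(self.per_type.values())

    def cumulative(self) -> pd.DataFrame:
        """Running totals per type at each release date."""
        out = self.per_release.copy()
        for ctype in CHANGE_TYPES:
            out[ctype] = out[ctype].cumsum()
        return out


def tabulate_changes(
    log: ChangeLog,
    from_date: _dt.date | None = None,
    to_date: _dt.date | None = None,
) -> ChangeSummary:
    """Count change events per type within an inclusive date window."""
    windowed = log.window(from_date, to_date)
    per_type = {t: 0 for t in CHANGE_TYPES}
    by_release: dict[_dt.date, dict[str, int]] = {}
    for e in windowed.events:
        per_type[e.change_type] += 1
        by_release.setdefault(e.release_date, {t: 0 for t in CHANGE_TYPES})
        by_release[e.release_date][e.change_type] += 1
    rows = [
        {"release_date": d, **counts} for d, counts in sorted(by_release.items())
    ]
    per_release = pd.DataFrame(rows, columns=["release_date", *CHANGE_TYPES])
    return ChangeSummary(per_type=per_type, per_release=per_release)


@dataclass(frozen=True)
class IntervalStats:
    """Update-interval statistics of a release history, in fractional weeks."""

    mean_interval_weeks: float
    mean_changes_per_update: float
    p90_interval_weeks: float
    p90_changes_per_update: float


def _nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Empirical q-th percentile, nearest-rank definition (no interpolation)."""
    if not values:
        raise ValueError("percentile of empty sequence")
    ordered = sorted(values)
    rank = math.ceil(q / 100.0 * len(ordered))
    return ordered[max(rank, 1) - 1]


def update_interval_stats(log: ChangeLog) -> IntervalStats:
    """Mean and 90th-percentile release interval (weeks) and changes per update.

    Intervals are successive release-date gaps in fractional weeks (days/7);
    changes per update counts events at each release after the first.
    Requires at least two distinct release dates.
    """
    dates = log.release_dates
    if len(dates) < 2:
        raise ValueError("need at least 2 distinct release dates")
    intervals = [(b - a).days / 7.0 for a, b in zip(dates, dates[1:])]
    counts_by_date: dict[_dt.date, int] = {d: 0 for d in dates}
    for e in log.events:
        counts_by_date[e.release_date] += 1
    changes_per_update = [counts_by_date[d] for d in dates[1:]]
    return IntervalStats(
        mean_interval_weeks=sum(intervals) / len(intervals),
        mean_changes_per_update=sum(changes_per_update) / len(changes_per_update),
        p90_interval_weeks=_nearest_rank_percentile(intervals, 90),
        p90_changes_per_update=_nearest_rank_percentile(changes_per_update, 90),
    )


@dataclass
class SynonymMap:
    """Maps gene/allele names with identical sequences to one canonical name.

    Canonical is the lexicographically smallest name of each identical-
    sequence group; names outside any group (including unknown names)
    canonicalize to themselves, so the map is idempotent.
    """

    level: str = "gene"
    mapping: dict[str, str] = field(default_factory=dict)

    def canonical(self, name: str) -> str:
        if self.level == "gene":
            name = strip_allele(name)
        return self.mapping.get(name, name)

    def __len__(self) -> int:
        return len(self.mapping)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, canon in self.mapping.items():
            out.setdefault(canon, []).append(name)
        return {c: sorted(members) for c, members in out.items()}


def build_synonym_map(reference: ReferenceSet, level: str = "gene") -> SynonymMap:
    """Group names sharing an identical nucleotide sequence.

    At the allele level, groups are allele names with byte-identical
    sequences.  At the gene level, genes are grouped transitively: two genes
    belong together when any of their alleles carry the same sequence.
    """
    if level not in ("gene", "allele"):
        raise ValueError("level must be 'gene' or 'allele'")
    by_seq: dict[str, list[str]] = {}
    for a in reference.alleles:
        name = a.gene_name if level == "gene" else a.allele_name
        group = by_seq.setdefault(a.nt_sequence, [])
        if name not in group:
            group.append(name)

    # transitive union of groups sharing members (a gene may appear under
    # several sequences through its alleles)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for group in by_seq.values():
        for a, b in zip(group, group[1:]):
            union(a, b)

    clusters: dict[str, list[str]] = {}
    for name in parent:
        clusters.setdefault(find(name), []).append(name)
    mapping = {
        name: min(members)
        for root, members in clusters.items()
        if len(members) > 1
        for name in members
    }
    return SynonymMap(level=level, mapping=mapping)
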