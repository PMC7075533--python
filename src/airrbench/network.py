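"""CDR3 similarity networks and shared-CDR3 sub-network analysis.

Unique CDR3 amino-acid sequences are nodes; two nodes are linked when their
Levenshtein distance is exactly 1 (a single substitution, insertion or
deletion).  A node's degree counts its links — the number of CDR3s one
mutation away — and the network's average degree 2L/N separates repertoire
regimes: below 0.5 the repertoire is diverse (many isolated clonotypes),
above 0.5 polarized (dense mutational neighbourhoods around expanded
clones).

Sub-networks are node subsets shared between tools; their degrees are
measured in a chosen parent network (links to nodes outside the subset
still count), so the same shared CDR3s can score differently depending on
which tool's network they are embedded in.  An induced-subgraph variant is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "CDR3Network",
    "CorrelationResult",
    "levenshtein_leq1",
    "build_network",
    "classify_diversity",
    "shared_subnetwork_degrees",
    "degree_correlations",
]

DIVERSITY_THRESHOLD = 0.5


def levenshtein_leq1(a: str, b: str) -> bool:
    """True iff distinct strings a, b are within Levenshtein distance 1.

    Early-exit implementation equivalent to full unit-cost edit distance:
    a length difference above 1 rules the pair out; equal lengths allow at
    most one mismatched position; lengths differing by 1 require the
    shorter string to be the longer with one character deleted.
    """
    if not a or not b:
        raise ValueError("CDR3 strings must be non-empty")
    if a == b:
        return False  # identical strings are one node, never a link
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        mismatches = 0
        for ca, cb in zip(a, b):
            if ca != cb:
                mismatches += 1
                if mismatches > 1:
                    return False
        return True
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # len(b) == len(a) + 1: skip exactly one character of b
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


@dataclass
class CDR3Network:
    """A Levenshtein-distance-≤1 similarity network over unique CDR3s."""

    nodes: list[str]
    links: set[frozenset[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for link in self.links:
            for n in link:
                deg[n] += 1
        return deg

    @property
    def average_degree(self) -> float:
        if not self.nodes:
            return 0.0
        return 2.0 * len(self.links) / len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(link)) for link in self.links)
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = sorted(tuple(sorted(link)) for link in self.links)
        return pd.DataFrame(rows, columns=["source", "target"])


def build_network(cdr3s: Iterable[str]) -> CDR3Network:
    """Build the distance-≤1 network over a set of unique CDR3 strings.

    All unordered pairs are tested, with length-bucket pruning (only pairs
    whose lengths differ by at most 1 are compared); the pruning is an
    optimization only and is link-for-link identical to testing every pair.
    Duplicate or empty inputs are rejected.
    """
    nodes = list(cdr3s)
    if len(nodes) != len(set(nodes)):
        raise ValueError("CDR3 inputs must be unique")
    if any(not n for n in nodes):
        raise ValueError("CDR3 strings must be non-empty")
    by_length: dict[int, list[str]] = {}
    for n in sorted(nodes):
        by_length.setdefault(len(n), []).append(n)
    links: set[frozenset[str]] = set()
    for length, bucket in by_length.items():
        for i, a in enumerate(bucket):
            for b in bucket[i + 1:]:
                if levenshtein_leq1(a, b):
                    links.add(frozenset((a, b)))
        for b in by_length.get(length + 1, ()):
            for a in bucket:
                if levenshtein_leq1(a, b):
                    links.add(frozenset((a, b)))
    return CDR3Network(nodes=nodes, links=links)


def classify_diversity(network: CDR3Network) -> str:
    """Classify a repertoire by average degree: < 0.5 diverse, > 0.5 polarized."""
    if not network.nodes:
        raise ValueError("cannot classify an empty network")
    avg = network.average_degree
    if avg < DIVERSITY_THRESHOLD:
        return "diverse"
    if avg > DIVERSITY_THRESHOLD:
        return "polarized"
    return "boundary"


def shared_subnetwork_degrees(
    networks: Mapping[str, CDR3Network],
    subsets: Mapping[str, set[str]],
    induced: bool = False,
) -> pd.DataFrame:
    """Average degree of each shared-CDR3 subset in each parent network.

    Rows are parent networks (whose links supply the degrees), columns the
    shared-CDR3 subsets.  By default degrees come from the full parent
    network, links to nodes outside the subset included; ``induced=True``
    instead restricts to links internal to the subset.
    """
    rows = {}
    for tool, net in networks.items():
        deg = net.degree
        node_set = set(net.nodes)
        row = {}
        for label, subset in subsets.items():
            missing = subset - node_set
            if missing:
                raise ValueError(
                    f"subset {label!r} node {sorted(missing)[0]!r} missing "
                    f"from network {tool!r}"
                )
            if not subset:
                row[label] = float("nan")
                continue
            if induced:
                internal = [l for l in net.links if l <= subset]
                sub_deg = {n: 0 for n in subset}
                for link in internal:
                    for n in link:
                        sub_deg[n] += 1
                row[label] = sum(sub_deg.values()) / len(subset)
            else:
                row[label] = sum(deg[n] for n in subset) / len(subset)
        rows[tool] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r and Kendall tau-b between two aligned degree vectors."""

    r: float | None
    tau: float | None
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None and self.tau is not None


def degree_correlations(
    degrees_a: Sequence[float],
    degrees_b: Sequence[float],
) -> CorrelationResult:
    """Correlate two tools' degrees over the same shared CDR3s.

    Pearson is the product-moment coefficient; Kendall uses the tau-b tie
    correction, since degree vectors are heavily tied.  A constant vector
    leaves both undefined (returned as missing with a reason).
    """
    if len(degrees_a) != len(degrees_b):
        raise ValueError(
            f"degree vectors differ in length: {len(degrees_a)} vs {len(degrees_b)}"
        )
    n = len(degrees_a)
    if n < 3:
        raise ValueError("need at least 3 shared CDR3s to correlate degrees")
    if len(set(degrees_a)) == 1 or len(set(degrees_b)) == 1:
        return CorrelationResult(r=None, tau=None, n=n,
                                 reason="constant degree vector")
    r = float(stats.pearsonr(degrees_a, degrees_b).statistic)
    tau = float(stats.kendalltau(degrees_a, degrees_b, variant="b").statistic)
    return CorrelationResult(r=r, tau=tau, n=n)
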