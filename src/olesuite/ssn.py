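"""OleA sequence similarity network.

All-vs-all local alignment feeds two thresholds: members at > 75%
identity collapse into one node (single-linkage components, so the rule
is order-independent), and nodes are joined by an edge when any member
pair aligns at E < 1e-5. Edge weight stores the best member-pair score.
Cross-phylum edges flag lateral-transfer candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .align import ScoringScheme, local_align

DEFAULT_IDENTITY_COLLAPSE = 75.0
DEFAULT_EVALUE_EDGE = 1e-5


@dataclass(frozen=True)
class PairwiseRecord:
    id1: str
    id2: str
    score: int
    percent_identity: float
    evalue: float

    def __post_init__(self):
        if not self.id1 < self.id2:
            raise ValueError("pair must be ordered id1 < id2")


@dataclass(frozen=True)
class SSNNode:
    representative_id: str
    member_ids: tuple[str, ...]
    phylum: str | None = None


@dataclass
class SSN:
    nodes: list[SSNNode]
    edges: list[tuple[str, str, int]]  # (node1, node2, best member-pair score)
    identity_collapse: float = DEFAULT_IDENTITY_COLLAPSE
    evalue_edge: float = DEFAULT_EVALUE_EDGE
    unlabelled_nodes: int = 0

    def node_of(self, member_id: str) -> SSNNode:
        for node in self.nodes:
            if member_id in node.member_ids:
                return node
        raise KeyError(member_id)


def _shared_kmer_fraction(a: str, b: str, k: int = 4) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / min(len(ka), len(kb))


def all_vs_all(
    seqs: dict[str, str],
    scheme: ScoringScheme | None = None,
    prefilter: bool = False,
    prefilter_min_shared: float = 0.02,
) -> list[PairwiseRecord]:
    """Exactly n(n-1)/2 pairwise records, ordered by (id1, id2).

    With ``prefilter`` on, pairs sharing almost no 4-mers skip the full
    alignment and are recorded with identity 0 and E = inf; the shared-kmer
    cut is set far below what any >= 70%-identity pair can reach, so the
    collapse graph is unaffected (checked in the test suite).
    """
    ids = sorted(seqs)
    if len(ids) != len(set(ids)) or len(ids) < 2:
        raise ValueError("need >= 2 sequences with unique ids")
    scheme = scheme or ScoringScheme()
    records = []
    for i, id1 in enumerate(ids):
        for id2 in ids[i + 1 :]:
            if prefilter and _shared_kmer_fraction(seqs[id1], seqs[id2]) < prefilter_min_shared:
                records.append(PairwiseRecord(id1, id2, 0, 0.0, float("inf")))
                continue
            hit = local_align(seqs[id1], seqs[id2], scheme)
            records.append(
                PairwiseRecord(id1, id2, hit.score, hit.percent_identity, hit.evalue)
            )
    return records


def collapse_nodes(
    pairs: list[PairwiseRecord],
    identity_threshold: float = DEFAULT_IDENTITY_COLLAPSE,
    seq_lengths: dict[str, int] | None = None,
) -> dict[str, str]:
    """Single-linkage collapse of ids linked at identity strictly above threshold.

    Returns id -> representative id. The representative is the longest
    member (ties by lexicographically smallest id); without lengths, the
    smallest id.
    """
    g = nx.Graph()
    for p in pairs:
        g.add_node(p.id1)
        g.add_node(p.id2)
        if p.percent_identity > identity_threshold:
            g.add_edge(p.id1, p.id2)
    mapping: dict[str, str] = {}
    for comp in nx.connected_components(g):
        if seq_lengths:
            rep = min(comp, key=lambda i: (-seq_lengths.get(i, 0), i))
        else:
            rep = min(comp)
        for member in comp:
            mapping[member] = rep
    return mapping


def build_network(
    pairs: list[PairwiseRecord],
    collapse_map: dict[str, str],
    evalue_edge: float = DEFAULT_EVALUE_EDGE,
    phyla: dict[str, str] | None = None,
    identity_collapse: float = DEFAULT_IDENTITY_COLLAPSE,
) -> SSN:
    """Assemble the collapsed network with E < evalue_edge edges.

    Node phylum is taken from its members' labels (must agree); members
    without a label leave the node unlabelled and counted in
    ``unlabelled_nodes``.
    """
    members: dict[str, list[str]] = {}
    for member, rep in sorted(collapse_map.items()):
        members.setdefault(rep, []).append(member)
    phyla = phyla or {}
    nodes = []
    unlabelled = 0
    for rep, mem in sorted(members.items()):
        labels = {phyla[m] for m in mem if m in phyla}
        if len(labels) > 1:
            raise ValueError(f"node {rep} members span phyla {sorted(labels)}")
        if not labels:
            unlabelled += 1
        nodes.append(SSNNode(rep, tuple(mem), labels.pop() if labels else None))
    best_edge: dict[tuple[str, str], int] = {}
    for p in pairs:
        n1, n2 = collapse_map[p.id1], collapse_map[p.id2]
        if n1 == n2 or not p.evalue < evalue_edge:
            continue
        key = (min(n1, n2), max(n1, n2))
        if key not in best_edge or p.score > best_edge[key]:
            best_edge[key] = p.score
    edges = [(a, b, s) for (a, b), s in sorted(best_edge.items())]
    return SSN(nodes, edges, identity_collapse, evalue_edge, unlabelled)


def cross_taxon_edges(ssn: SSN) -> list[tuple[str, str, int]]:
    """Edges whose endpoint nodes carry different phylum labels.

    Lateral-transfer candidates; edges touching unlabelled nodes are
    skipped (their count is on the SSN itself).
    """
    label = {n.representative_id: n.phylum for n in ssn.nodes}
    return [
        (a, b, s) for a, b, s in ssn.edges
        if label[a] is not None and label[b] is not None and label[a] != label[b]
    ]


def to_edge_table(ssn: SSN):
    import pandas as pd

    return pd.DataFrame(ssn.edges, columns=["node1", "node2", "best_score"])


def to_graphml(ssn: SSN, path) -> None:
    g = nx.Graph()
    for node in ssn.nodes:
        g.add_node(
            node.representative_id,
            size=len(node.member_ids),
            members=";".join(node.member_ids),
            phylum=node.phylum or "",
        )
    for a, b, s in ssn.edges:
        g.add_edge(a, b, best_score=s)
    nx.write_graphml(g, path)
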