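"""Node and edge overlap between a topic-word network and a keyword network.

Both networks carry stemmed, lowercased names, but topic words are single
stems while author keywords may be multi-word ("forag" vs "foraging
behavior"), so matching admits contiguous substring containment in either
direction in addition to exact equality.  A minimum matched length of
3 characters guards against promiscuous 1-2 letter stems.  The overlap
fraction is computed over the *subject* network (conventionally the topic
network): matched subject elements / total subject elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

MIN_SUBSTRING_LEN = 3


def node_matches(a: str, b: str) -> bool:
    """Exact match, or containment of a >=3-character name either way."""
    if a == b:
        return True
    if len(a) >= MIN_SUBSTRING_LEN and a in b:
        return True
    if len(b) >= MIN_SUBSTRING_LEN and b in a:
        return True
    return False


@dataclass
class OverlapReport:
    """Overlap of a subject network with a reference network."""

    node_overlap_fraction: float
    edge_overlap_fraction: float
    node_matches: list[dict] = field(default_factory=list)
    edge_matches: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "node_overlap_fraction": self.node_overlap_fraction,
                    "edge_overlap_fraction": self.edge_overlap_fraction,
                    "node_matches": self.node_matches,
                    "edge_matches": self.edge_matches,
                },
                fh, indent=2,
            )


def node_overlap(subject: nx.Graph, reference: nx.Graph) -> tuple[float, list[dict]]:
    """Fraction of subject nodes with a matching reference node.

    Each subject node is counted once; a reference node may match several
    subject nodes (no bijection is enforced).
    """
    if subject.number_of_nodes() == 0:
        raise ValueError("subject network has no nodes; overlap undefined")
    ref_nodes = sorted(reference.nodes)
    matches = []
    for s in sorted(subject.nodes):
        for r in ref_nodes:
            if node_matches(s, r):
                matches.append(
                    {"subject": s, "reference": r,
                     "type": "exact" if s == r else "substring"}
                )
                break
    return len(matches) / subject.number_of_nodes(), matches


def _edge_case(sa: str, sb: str, ra: str, rb: str) -> int:
    exact = (sa == ra) + (sb == rb)
    return {2: 1, 1: 2, 0: 3}[exact]


def edge_overlap(subject: nx.Graph, reference: nx.Graph) -> tuple[float, list[dict]]:
    """Fraction of subject edges matching a reference edge.

    A subject edge {a, b} matches reference edge {c, d} if the endpoints
    can be aligned so both match under the node rules.  Matching is greedy
    first-match over lexicographically sorted reference edges; case 1 =
    both exact, 2 = one exact one substring, 3 = both substring.
    """
    if subject.number_of_edges() == 0:
        raise ValueError("subject network has no edges; overlap undefined")
    ref_edges = sorted(tuple(sorted(e)) for e in reference.edges)
    matches = []
    for sa, sb in sorted(tuple(sorted(e)) for e in subject.edges):
        for ra, rb in ref_edges:
            if node_matches(sa, ra) and node_matches(sb, rb):
                align = (ra, rb)
            elif node_matches(sa, rb) and node_matches(sb, ra):
                align = (rb, ra)
            else:
                continue
            matches.append(
                {"subject": [sa, sb], "reference": [ra, rb],
                 "case": _edge_case(sa, sb, *align)}
            )
            break
    return len(matches) / subject.number_of_edges(), matches


def compare_networks(subject: nx.Graph, reference: nx.Graph) -> OverlapReport:
    """Full node + edge overlap report (subject vs reference)."""
    nfrac, nmatch = node_overlap(subject, reference)
    efrac, ematch = edge_overlap(subject, reference)
    return OverlapReport(
        node_overlap_fraction=nfrac,
        edge_overlap_fraction=efrac,
        node_matches=nmatch,
        edge_matches=ematch,
    )
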