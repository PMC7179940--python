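"""Highly related pair extraction and identity groups.

Scores above the relatedness threshold define an undirected graph whose
nodes are individual omics datasets ("data") and whose edges are highly
related data pairs.  Connected components of that graph ("groups") are
presumed to originate from a single individual; edges within a group are
*matched* when the two data carry the same observed ID and *mismatched*
otherwise.  Data touching no edge are unassignable and reported separately.

Stringent mode additionally discards groups that are nearly hopeless to
re-align: fewer than three data, or no ID shared by at least two data.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .relatedness import DEFAULT_THRESHOLD, RelatednessTable

__all__ = [
    "DataNode",
    "PairEdge",
    "Group",
    "extract_high_pairs",
    "build_groups",
    "stringent_filter",
    "summarize_pairs",
    "write_cytoscape_edges",
]

log = logging.getLogger(__name__)


@dataclass(eq=False)
class DataNode:
    """One omics dataset instance — the unit being re-aligned.

    ``data_id`` is the *observed* (possibly wrong) identifier.  Nodes are
    compared by identity, never by value: two nodes with equal fields are
    still distinct data.
    """

    data_id: str
    omics_type: str
    reported_sex: str = "unknown"
    snp_sex: str = "unknown"
    omics_priority: float = 0.5

    @property
    def key(self) -> tuple[str, str]:
        return (self.data_id, self.omics_type)

    def __repr__(self) -> str:  # compact for debugging group structures
        return f"DataNode({self.data_id}|{self.omics_type})"


@dataclass(eq=False)
class PairEdge:
    """A highly related data pair.

    ``status`` is ``matched`` iff both sides carry the same observed ID;
    matched edges never receive a direction or weight.  For mismatched
    edges the re-alignment step fills ``direction`` (``a_to_b`` means B is
    the more plausible true ID) and ``weight`` in [0, 1].
    """

    a: DataNode
    b: DataNode
    score: float = 1.0
    status: str = ""
    direction: str = "none"
    weight: float = 0.0

    def __post_init__(self) -> None:
        if not self.status:
            self.status = "matched" if self.a.data_id == self.b.data_id else "mismatched"
        if self.status == "matched":
            self.direction = "none"
            self.weight = 0.0

    def other(self, node: DataNode) -> DataNode:
        if node is self.a:
            return self.b
        if node is self.b:
            return self.a
        raise ValueError("node is not an endpoint of this edge")


@dataclass(eq=False)
class Group:
    """A maximal connected component of highly related data."""

    group_id: int
    nodes: list[DataNode]
    edges: list[PairEdge]
    discarded: bool = False
    discard_reason: str = "none"
    notes: list[str] = field(default_factory=list)


def extract_high_pairs(
    table: RelatednessTable,
    threshold: float = DEFAULT_THRESHOLD,
    nodes: Mapping[tuple[str, str], DataNode] | None = None,
) -> list[PairEdge]:
    """One edge per table row with score strictly above ``threshold``.

    ``nodes`` optionally maps ``(data_id, omics_type)`` to pre-built
    :class:`DataNode` objects (carrying sexes and priorities); missing nodes
    are created on the fly with default attributes.
    """
    if len(table) == 0:
        raise ValueError("empty relatedness table")
    registry: dict[tuple[str, str], DataNode] = dict(nodes) if nodes else {}
    edges: list[PairEdge] = []
    for row in table.df.itertuples(index=False):
        if not row.score > threshold:
            continue
        ka = (row.data_a, row.omics_a)
        kb = (row.data_b, row.omics_b)
        if ka not in registry:
            registry[ka] = DataNode(row.data_a, row.omics_a)
        if kb not in registry:
            registry[kb] = DataNode(row.data_b, row.omics_b)
        edges.append(PairEdge(registry[ka], registry[kb], score=float(row.score)))
    return edges


def build_groups(
    nodes: Sequence[DataNode], edges: Sequence[PairEdge]
) -> tuple[list[Group], list[DataNode]]:
    """Connected components of the edge-induced graph.

    Returns ``(groups, isolated)`` where isolated nodes touch no edge.
    Group ids are assigned deterministically in order of each component's
    first node in ``nodes``.
    """
    index = {id(n): i for i, n in enumerate(nodes)}
    for e in edges:
        if id(e.a) not in index or id(e.b) not in index:
            raise ValueError("edge endpoint not present in the node list")

    adjacency: dict[int, list[PairEdge]] = defaultdict(list)
    for e in edges:
        adjacency[id(e.a)].append(e)
        adjacency[id(e.b)].append(e)

    seen: set[int] = set()
    groups: list[Group] = []
    isolated: list[DataNode] = []
    for node in nodes:
        if id(node) in seen:
            continue
        if not adjacency[id(node)]:
            seen.add(id(node))
            isolated.append(node)
            continue
        # breadth-first walk over this component
        comp_nodes: list[DataNode] = []
        comp_edges: list[PairEdge] = []
        edge_ids: set[int] = set()
        stack = [node]
        seen.add(id(node))
        while stack:
            cur = stack.pop()
            comp_nodes.append(cur)
            for e in adjacency[id(cur)]:
                if id(e) not in edge_ids:
                    edge_ids.add(id(e))
                    comp_edges.append(e)
                nxt = e.other(cur)
                if id(nxt) not in seen:
                    seen.add(id(nxt))
                    stack.append(nxt)
        comp_nodes.sort(key=lambda n: index[id(n)])
        groups.append(Group(len(groups) + 1, comp_nodes, comp_edges))
    return groups, isolated


def stringent_filter(groups: Iterable[Group]) -> list[Group]:
    """Mark hopeless groups as discarded (idempotent).

    A group is discarded when it holds fewer than three data
    (``too_small``) or when all observed IDs in it are pairwise distinct
    (``no_shared_id``).  Groups containing two or more distinct IDs that
    each label several data (possible contamination bridge, e.g. related
    individuals) are kept but annotated.
    """
    out = []
    for g in groups:
        counts = Counter(n.data_id for n in g.nodes)
        if len(g.nodes) < 3:
            g.discarded = True
            g.discard_reason = "too_small"
        elif all(c == 1 for c in counts.values()):
            g.discarded = True
            g.discard_reason = "no_shared_id"
        else:
            g.discarded = False
            g.discard_reason = "none"
            multi = [i for i, c in counts.items() if c >= 2]
            note = (
                f"multiple matched-ID cliques ({', '.join(sorted(multi))}); "
                "check for related individuals"
            )
            if len(multi) >= 2 and note not in g.notes:
                g.notes.append(note)
        out.append(g)
    return out


def summarize_pairs(edges: Iterable[PairEdge]) -> dict[tuple[str, str, str], int]:
    """Matched/mismatched edge counts per unordered omics pair."""
    counts: Counter = Counter()
    for e in edges:
        oa, ob = sorted((e.a.omics_type, e.b.omics_type))
        counts[(oa, ob, e.status)] += 1
    return dict(counts)


def write_cytoscape_edges(edges: Iterable[PairEdge], path: str | Path) -> None:
    """Write a network-viewer-friendly edge list (TSV).

    Nodes are encoded as ``data_id|omics_type`` so distinct data with the
    same observed ID stay distinct in the display.
    """
    with open(path, "w") as fh:
        fh.write("source\ttarget\tstatus\tscore\tdirection\tweight\n")
        for e in edges:
            fh.write(
                f"{e.a.data_id}|{e.a.omics_type}\t{e.b.data_id}|{e.b.omics_type}\t"
                f"{e.status}\t{e.score:.6g}\t{e.direction}\t{e.weight:.6g}\n"
            )
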