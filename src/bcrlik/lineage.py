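"""Germline-rooted clonal lineage trees over unique sequences.

Each clone's unique (heavy, or concatenated heavy+light) sequences are grown
into a tree from the germline root by iterative minimum-distance attachment:
the unattached sequence whose minimum Levenshtein distance to any attached
node is smallest joins as a child of that nearest node. This is Prim's
algorithm on the complete Levenshtein graph, so the total edge weight of the
resulting tree equals the minimum-spanning-tree weight regardless of
attachment order; only tie topology can vary, and ties are broken
deterministically (prefer the more expanded candidate parent, then the
lexicographically smaller child sequence, then earlier-attached parents).

Levenshtein distances come from edlib (unit-cost substitutions, insertions
and deletions), so clones containing indel variants still form trees; such
edges are only excluded later, in the edge-substitution analysis.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping

import edlib
import networkx as nx
import pandas as pd

from .errors import DataError
from .records import Repertoire

ROOT_ID = "germline"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two amino-acid strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


class LineageTree:
    """A germline-rooted tree over the unique sequences of one clone."""

    def __init__(self, clone_id: str, graph: nx.DiGraph, root: str = ROOT_ID):
        self.clone_id = clone_id
        self.graph = graph
        self.root = root
        self._node_by_sequence = {
            data["sequence"]: node for node, data in graph.nodes(data=True)
        }

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def sequence(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["sequence"]

    def cell_count(self, node_id: str) -> int:
        return self.graph.nodes[node_id]["cell_count"]

    def node_of(self, sequence: str) -> str | None:
        return self._node_by_sequence.get(sequence)

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())

    def root_path_length(self, node_id: str) -> int:
        """Sum of edge weights on the unique root -> node path."""
        if node_id not in self.graph:
            raise DataError(f"node {node_id!r} not in tree {self.clone_id}")
        total = 0
        while node_id != self.root:
            parent = next(iter(self.graph.predecessors(node_id)))
            total += self.graph[parent][node_id]["weight"]
            node_id = parent
        return total

    # -- export ------------------------------------------------------------
    def to_newick(self) -> str:
        def render(node: str) -> str:
            children = sorted(self.graph.successors(node))
            label = node
            if not children:
                return label
            inner = ",".join(
                f"{render(c)}:{self.graph[node][c]['weight']}" for c in children
            )
            return f"({inner}){label}"

        return render(self.root) + ";"

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append(
                {
                    "clone_id": self.clone_id,
                    "node_id": node,
                    "sequence": data["sequence"],
                    "cell_count": data["cell_count"],
                    "isotypes": ";".join(
                        f"{iso}:{n}" for iso, n in sorted(data.get("isotypes", Counter()).items())
                    ),
                    "root_path_length": self.root_path_length(node),
                }
            )
        return pd.DataFrame(rows)


def build_tree(
    clone_sequences: Mapping[str, int],
    germline: str,
    clone_id: str = "clone",
    isotypes: Mapping[str, Counter] | None = None,
) -> LineageTree:
    """Grow a germline-rooted tree by iterative minimum-distance attachment.

    ``clone_sequences`` maps each unique member sequence to its cell count
    (duplicates must be pre-merged — the mapping enforces this). A member
    sequence identical to the germline merges into the root node, whose
    cell count is otherwise 0.
    """
    if not germline:
        raise DataError("empty germline")
    counts = dict(clone_sequences)
    if any(n < 1 for n in counts.values()):
        raise DataError("cell counts must be >= 1")
    root_count = counts.pop(germline, 0)
    if not counts:
        raise DataError("need at least one unique non-germline sequence")

    graph = nx.DiGraph()
    graph.add_node(
        ROOT_ID,
        sequence=germline,
        cell_count=root_count,
        isotypes=(isotypes or {}).get(germline, Counter()),
    )
    attached: dict[str, str] = {ROOT_ID: germline}  # node_id -> sequence
    attach_order = [ROOT_ID]
    remaining = sorted(counts)
    dist: dict[tuple[str, str], int] = {}

    n = 0
    while remaining:
        best = None  # (distance, -parent_cell_count, child_seq, parent_rank)
        for child in remaining:
            for rank, pid in enumerate(attach_order):
                pair = (child, pid)
                if pair not in dist:
                    dist[pair] = levenshtein(child, attached[pid])
                key = (dist[pair], -graph.nodes[pid]["cell_count"], child, rank)
                if best is None or key < best[0]:
                    best = (key, child, pid)
        (_, child, pid) = best
        n += 1
        node_id = f"n{n}"
        graph.add_node(
            node_id,
            sequence=child,
            cell_count=counts[child],
            isotypes=(isotypes or {}).get(child, Counter()),
        )
        graph.add_edge(pid, node_id, weight=dist[(child, pid)])
        attached[node_id] = child
        attach_order.append(node_id)
        remaining.remove(child)

    return LineageTree(clone_id, graph)


def build_forest(rep: Repertoire, chains: str = "heavy") -> dict[str, LineageTree]:
    """One lineage tree per clone with at least one non-germline sequence.

    ``chains`` is "heavy" (default) or "paired" (heavy+light concatenation,
    used for intraclonal affinity analyses). The clone germline is the most
    common member germline; clones whose members all equal the germline are
    skipped (a single root is not a lineage).
    """
    if chains not in ("heavy", "paired"):
        raise DataError(f"chains must be 'heavy' or 'paired', got {chains!r}")
    forest: dict[str, LineageTree] = {}
    for clone_id, members in rep.clones().items():
        counts: Counter = Counter()
        iso: dict[str, Counter] = {}
        germs: Counter = Counter()
        for cell in members:
            if chains == "heavy":
                seq = cell.heavy.sequence_aa
                germ = cell.heavy.germline_aa
            else:
                seq = cell.heavy.sequence_aa + cell.light.sequence_aa
                germ = cell.heavy.germline_aa + cell.light.germline_aa
            counts[seq] += 1
            iso.setdefault(seq, Counter())[cell.isotype] += 1
            if germ:
                germs[germ] += 1
        if not germs:
            continue
        germline = germs.most_common(1)[0][0]
        if set(counts) == {germline}:
            continue
        forest[clone_id] = build_tree(counts, germline, clone_id=clone_id, isotypes=iso)
    return forest


def write_forest(forest: Mapping[str, LineageTree], out_dir: str | Path) -> dict[str, Path]:
    """Newick file per clone plus one combined node attribute table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    newick = out_dir / "forest.nwk"
    with newick.open("w") as fh:
        for clone_id in sorted(forest):
            fh.write(f"# {clone_id}\n{forest[clone_id].to_newick()}\n")
    nodes = out_dir / "nodes.csv"
    tables = [forest[c].node_table() for c in sorted(forest)]
    (pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()).to_csv(
        nodes, index=False
    )
    return {"newick": newick, "nodes": nodes}
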