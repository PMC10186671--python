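"""Haplotype network construction.

Nodes are haplotypes (sized by frequency, optionally coloured by the group
composition of their member accessions); links carry the number of variant
sites separating the two haplotypes (Hamming distance over genotype
vectors — each differing site counts one step regardless of allele
length).  The primary links form a minimum spanning tree computed with
Kruskal's algorithm under a deterministic edge order (ascending distance,
then the lexicographically smallest node-name pair), so identical input
always yields an identical edge list.  Non-tree edges no longer than the
longest tree edge plus ``epsilon`` are kept as flagged alternative links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AccessionTable, HapSummary


@dataclass(frozen=True)
class Link:
    """An undirected link between two haplotypes carrying mutation steps."""

    a: str
    b: str
    steps: int


@dataclass
class HaploNetwork:
    """Haplotype network: nodes with frequencies/group pies, MST links."""

    nodes: list[str]
    freqs: dict[str, int]
    groups: dict[str, dict[str, int]]
    links: list[Link]
    alt_links: list[Link] = field(default_factory=list)

    def total_weight(self) -> int:
        return sum(l.steps for l in self.links)

    def to_edge_list(self) -> str:
        """Tab-delimited edge list (primary then alternative links)."""
        lines = ["hapA\thapB\tsteps\tkind"]
        for l in self.links:
            lines.append(f"{l.a}\t{l.b}\t{l.steps}\tprimary")
        for l in self.alt_links:
            lines.append(f"{l.a}\t{l.b}\t{l.steps}\talternative")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        """GraphViz DOT rendering with step counts as edge labels."""
        out = ["graph haplonet {"]
        for n in self.nodes:
            out.append(f'  "{n}" [width={self.freqs[n]}];')
        for l in self.links:
            out.append(f'  "{l.a}" -- "{l.b}" [label={l.steps}];')
        for l in self.alt_links:
            out.append(f'  "{l.a}" -- "{l.b}" [label={l.steps}, style=dashed];')
        out.append("}")
        return "\n".join(out) + "\n"


def pairwise_distances(hs: HapSummary) -> pd.DataFrame:
    """Symmetric Hamming-distance matrix over haplotype genotype vectors."""
    if hs.n_hap < 2:
        raise ValueError("need at least two haplotypes for a distance matrix")
    lengths = {len(v) for v in hs.genotypes}
    if len(lengths) != 1:
        raise ValueError("genotype vectors have unequal lengths")
    vecs = np.array([list(v) for v in hs.genotypes], dtype=object)
    n = len(vecs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int(np.sum(vecs[i] != vecs[j]))
    return pd.DataFrame(d, index=hs.hap_names, columns=hs.hap_names)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def build_network(hs: HapSummary, groups: AccessionTable | None = None,
                  epsilon: int = 0, group_column: str | None = None) -> HaploNetwork:
    """Build the haplotype network from a summary table.

    Parameters
    ----------
    hs
        Haplotype summary (one row per haplotype, with member lists).
    groups
        Optional accession metadata supplying a group/category label per
        accession for the node pies; the first non-numeric column is used
        unless ``group_column`` names one.  Without it every node carries a
        single "ungrouped" category.
    epsilon
        Slack (extra mutation steps) for alternative links: every non-tree
        pair at distance <= longest tree edge + epsilon is reported as a
        flagged alternative link.  0 keeps the tree only.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    dist = pairwise_distances(hs)
    names = list(dist.index)

    edges = sorted(
        ((int(dist.at[a, b]), a, b)
         for i, a in enumerate(names) for b in names[i + 1:]),
        key=lambda e: (e[0], e[1], e[2]))
    uf = _UnionFind(names)
    tree, rest = [], []
    for w, a, b in edges:
        (tree if uf.union(a, b) else rest).append(Link(a, b, w))
    max_step = max((l.steps for l in tree), default=0)
    alt = [l for l in rest if l.steps <= max_step + epsilon]

    comp = _group_composition(hs, groups, group_column)
    return HaploNetwork(nodes=names, freqs=dict(zip(hs.hap_names, hs.freqs)),
                        groups=comp, links=tree, alt_links=alt)


def _group_composition(hs: HapSummary, groups: AccessionTable | None,
                       group_column: str | None) -> dict[str, dict[str, int]]:
    if groups is None:
        return {n: {"ungrouped": f} for n, f in zip(hs.hap_names, hs.freqs)}
    if group_column is None:
        cands = groups.group_columns()
        if not cands:
            return {n: {"ungrouped": f} for n, f in zip(hs.hap_names, hs.freqs)}
        group_column = cands[0]
    labels = groups.table[group_column]
    comp: dict[str, dict[str, int]] = {}
    for name, accs in zip(hs.hap_names, hs.accession_lists):
        d: dict[str, int] = {}
        for acc in accs:
            lab = str(labels.get(acc, "unknown"))
            if lab in ("nan", "None"):
                lab = "unknown"
            d[lab] = d.get(lab, 0) + 1
        comp[name] = d
    return comp


__all__ = ["Link", "HaploNetwork", "pairwise_distances", "build_network"]
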