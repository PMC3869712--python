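"""Haplotype networks and the delimitation statistics read off them.

Nodes are collapsed haplotypes; edge weights count nucleotide differences
(pairwise-deletion Hamming steps).  The network is a minimum spanning
network: a minimum-spanning-tree construction that keeps every co-minimal
tie edge, optionally thresholded by a maximum step count, which may split
the graph into separate clades.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import AnalysisError, LabelingError, UndefinedDistanceError
from .distances import encode
from .seqio import Haplotype, HaplotypeSet


def pairwise_steps(h: HaplotypeSet) -> tuple[tuple[str, ...], np.ndarray]:
    """Step matrix: per pair, the count of columns where both haplotypes are
    resolved (A/C/G/T) and differ."""
    ids = h.hap_ids
    codes = np.stack([encode(hap.sequence) for hap in h.haplotypes])
    n = len(ids)
    steps = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            if not valid.any():
                raise UndefinedDistanceError(
                    "no comparable sites", pair=(ids[i], ids[j])
                )
            d = int(((codes[i] != codes[j]) & valid).sum())
            steps[i, j] = steps[j, i] = d
    return ids, steps


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_network(h: HaplotypeSet, max_steps: int | None = None) -> nx.Graph:
    """Minimum spanning network over the haplotypes.

    Kruskal-style construction processing edges in increasing weight
    classes; within a class, every edge joining components as they stood at
    the start of the class is retained (so tied alternatives survive).
    Edges heavier than ``max_steps`` are then removed, possibly
    disconnecting the graph.
    """
    if len(h) < 1:
        raise AnalysisError("network needs at least one haplotype")
    ids, steps = pairwise_steps(h)
    g = nx.Graph()
    for hap in h.haplotypes:
        g.add_node(
            hap.hap_id,
            multiplicity=hap.multiplicity,
            members=",".join(hap.members),
            species=";".join(sorted(h.group_labels(hap, "species"))),
            populations=";".join(sorted(h.group_labels(hap, "population"))),
        )
    if len(h) == 1:
        return g
    edges = sorted(
        ((int(steps[i, j]), ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))),
    )
    dsu = _DSU(ids)
    k = 0
    while k < len(edges):
        w = edges[k][0]
        # snapshot of components at the start of this weight class
        comp = {x: dsu.find(x) for x in ids}
        added = []
        while k < len(edges) and edges[k][0] == w:
            _, a, b = edges[k]
            if comp[a] != comp[b]:
                g.add_edge(a, b, steps=w)
                added.append((a, b))
            k += 1
        for a, b in added:
            dsu.union(a, b)
    if max_steps is not None:
        heavy = [(a, b) for a, b, d in g.edges(data="steps") if d > max_steps]
        g.remove_edges_from(heavy)
    return g


def components(g: nx.Graph) -> list[frozenset[str]]:
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def min_steps_between(
    h: HaplotypeSet, group_a: str, group_b: str, by: str = "species"
) -> int:
    """Minimum step count over all cross-group haplotype pairs."""
    ids, steps = pairwise_steps(h)
    in_a = [k for k, hap in enumerate(h.haplotypes) if group_a in h.group_labels(hap, by)]
    in_b = [k for k, hap in enumerate(h.haplotypes) if group_b in h.group_labels(hap, by)]
    if not in_a:
        raise LabelingError(f"unknown group label: {group_a!r}")
    if not in_b:
        raise LabelingError(f"unknown group label: {group_b!r}")
    best = None
    for i in in_a:
        for j in in_b:
            if i == j:
                return 0  # a shared haplotype
            if best is None or steps[i, j] < best:
                best = int(steps[i, j])
    return best


@dataclass(frozen=True)
class SharedHaplotype:
    hap_id: str
    groups: frozenset[str]
    multiplicity: int


def shared_haplotypes(h: HaplotypeSet, by: str = "species") -> list[SharedHaplotype]:
    """Haplotypes whose members span more than one group label."""
    out = []
    for hap in h.haplotypes:
        groups = h.group_labels(hap, by)
        if len(groups) > 1:
            out.append(
                SharedHaplotype(hap_id=hap.hap_id, groups=groups, multiplicity=hap.multiplicity)
            )
    return out


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hap_a", "hap_b", "steps"])
        for a, b, d in sorted(g.edges(data="steps")):
            w.writerow([a, b, d])


def write_node_table(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hap_id", "multiplicity", "species", "populations", "members"])
        for node, data in sorted(g.nodes(data=True)):
            w.writerow(
                [node, data["multiplicity"], data["species"], data["populations"], data["members"]]
            )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
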