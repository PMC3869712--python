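"""Neighbor-joining trees, nonparametric bootstrap and monophyly checks.

The tree is unrooted; a label set is monophyletic iff it is one side of
some edge bipartition.  Negative NJ branch lengths are clamped to zero
with the deficit moved to the sister branch.  Q-matrix ties are broken by
the lexicographically smallest node-name pair for reproducibility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, DistanceError, LabelingError
from .distances import DistanceMatrix, distance_matrix_from_codes, encode_alignment
from .seqio import Alignment


@dataclass
class Tree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adj: dict[str, dict[str, float]]
    leaves: frozenset[str]
    support: dict[frozenset, float] | None = None
    n_dropped_replicates: int = 0

    def _ref_leaf(self) -> str:
        return min(self.leaves)

    def canonical(self, side: frozenset) -> frozenset:
        """Canonical key of a bipartition: the side excluding the reference leaf."""
        return frozenset(self.leaves - side) if self._ref_leaf() in side else frozenset(side)

    def _leafsets(self, root: str | None = None) -> dict[tuple[str, str], frozenset]:
        """Leaf set on the child side of every directed edge (parent, child)
        of a DFS rooted at ``root`` (arbitrary by default)."""
        if root is None:
            root = next(iter(self.adj))
        sets: dict[tuple[str, str], frozenset] = {}

        order: list[tuple[str, str]] = []
        stack = [(root, None)]
        seen = {root}
        while stack:
            node, parent = stack.pop()
            if parent is not None:
                order.append((parent, node))
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node))
        for parent, child in reversed(order):
            s = {child} if child in self.leaves else set()
            for nb in self.adj[child]:
                if nb != parent and (child, nb) in sets:
                    s |= sets[(child, nb)]
            sets[(parent, child)] = frozenset(s)
        return sets

    def bipartitions(self) -> dict[frozenset, tuple[str, str]]:
        """Canonical internal-edge bipartitions -> a witness edge."""
        n = len(self.leaves)
        out: dict[frozenset, tuple[str, str]] = {}
        for (parent, child), side in self._leafsets().items():
            if 2 <= len(side) <= n - 2:
                out.setdefault(self.canonical(side), (parent, child))
        return out

    def to_newick(self, include_support: bool = True, decimals: int = 8) -> str:
        root = next((n for n in self.adj if n not in self.leaves), None)
        if root is None:  # 2-leaf or degenerate tree
            root = next(iter(self.adj))
        sets = self._leafsets(root)

        def label(parent: str, child: str) -> str:
            if not include_support or self.support is None:
                return ""
            side = sets[(parent, child)]
            key = self.canonical(side)
            if key in self.support:
                return str(int(round(self.support[key])))
            return ""

        def render(node: str, parent: str | None) -> str:
            children = [nb for nb in self.adj[node] if nb != parent]
            if not children:
                return node
            inner = ",".join(
                f"{render(c, node)}:{self.adj[node][c]:.{decimals}f}" for c in children
            )
            lab = label(parent, node) if parent is not None else ""
            return f"({inner}){lab}"

        return render(root, None) + ";"

    def write_newick(self, path: str | Path, include_support: bool = True) -> None:
        Path(path).write_text(self.to_newick(include_support=include_support) + "\n")


def nj(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Exactly reconstructs additive metrics; deterministic under input-order
    permutation thanks to lexicographic tie-breaking.
    """
    n = len(dm)
    if n < 3:
        raise AnalysisError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise AnalysisError("distance matrix contains non-finite entries")
    names = list(dm.ids)
    D = dm.d.astype(float).copy()
    adj: dict[str, dict[str, float]] = {name: {} for name in names}
    next_internal = 0

    def connect(a: str, b: str, length: float) -> None:
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    while len(names) > 3:
        m = len(names)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=0))
        pairs = sorted(
            {tuple(sorted((names[i], names[j]))) for i, j in cand if i != j}
        )
        a_name, b_name = pairs[0]
        i, j = names.index(a_name), names.index(b_name)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        new_name = f"_nj{next_internal}"
        next_internal += 1
        connect(new_name, names[i], li)
        connect(new_name, names[j], lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        names = [names[k] for k in keep] + [new_name]

    # final three nodes: star join via the three-point formula
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    center = f"_nj{next_internal}"
    connect(center, names[0], max(la, 0.0))
    connect(center, names[1], max(lb, 0.0))
    connect(center, names[2], max(lc, 0.0))
    return Tree(adj=adj, leaves=frozenset(dm.ids))


def bootstrap(
    aln: Alignment, n_reps: int = 1000, seed: int | None = None
) -> Tree:
    """NJ tree with column-resampling bootstrap support.

    Support on each original internal bipartition is the percentage of
    completed replicates containing it.  Replicates with an undefined pair
    distance are dropped and counted on the returned tree.
    """
    codes = encode_alignment(aln)
    dm = distance_matrix_from_codes(codes, aln.ids)
    tree = nj(dm)
    if n_reps == 0:
        return tree
    orig_bips = list(tree.bipartitions())
    counts = {b: 0 for b in orig_bips}
    rng = np.random.default_rng(seed)
    completed = 0
    dropped = 0
    L = codes.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        try:
            dm_rep = distance_matrix_from_codes(codes[:, cols], aln.ids)
            tree_rep = nj(dm_rep)
        except DistanceError:
            dropped += 1
            continue
        rep_bips = set(tree_rep.bipartitions())
        completed += 1
        for b in orig_bips:
            if b in rep_bips:
                counts[b] += 1
    if completed == 0:
        raise AnalysisError("every bootstrap replicate failed")
    tree.support = {b: 100.0 * c / completed for b, c in counts.items()}
    tree.n_dropped_replicates = dropped
    return tree


@dataclass(frozen=True)
class MonophylyResult:
    label: str
    monophyletic: bool
    witness_edge: tuple[str, str] | None
    violators: tuple[str, ...]


def monophyly(
    tree: Tree, labels: Mapping[str, str], label_of_interest: str
) -> MonophylyResult:
    """Is the leaf set carrying a label one side of some edge bipartition?

    Single-leaf labels (and a label covering every leaf) are monophyletic
    by convention.  Otherwise, the reported violators are the symmetric
    difference with the closest-matching edge side.
    """
    missing = [l for l in tree.leaves if l not in labels]
    if missing:
        raise LabelingError(f"leaves missing a label: {', '.join(sorted(missing))}")
    target = frozenset(l for l in tree.leaves if labels[l] == label_of_interest)
    if not target:
        raise LabelingError(f"label not present on any leaf: {label_of_interest!r}")
    if len(target) == 1 or target == tree.leaves:
        return MonophylyResult(label_of_interest, True, None, ())
    best_diff: set | None = None
    for (parent, child), side in tree._leafsets().items():
        for s in (side, tree.leaves - side):
            if s == target:
                return MonophylyResult(label_of_interest, True, (parent, child), ())
            diff = set(s) ^ set(target)
            if best_diff is None or len(diff) < len(best_diff):
                best_diff = diff
    return MonophylyResult(
        label_of_interest, False, None, tuple(sorted(best_diff or ()))
    )


def monophyly_report(
    tree: Tree, labels: Mapping[str, str]
) -> list[MonophylyResult]:
    return [monophyly(tree, labels, lab) for lab in sorted(set(labels.values()))]


def monophyly_to_tsv(results: Sequence[MonophylyResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["label", "monophyletic", "violators"])
        for r in results:
            w.writerow([r.label, int(r.monophyletic), ";".join(r.violators)])
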