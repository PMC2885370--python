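"""Neighbor-joining trees and the tree-based (NJT) identification criterion.

NJT scores a query as correctly identified when the query and all its
conspecific sequences form a monospecific clade on a neighbor-joining tree
built from the K2P distance matrix.  On an unrooted tree "forms a clade" is
read as a bipartition test: species S is monospecific iff some edge splits
the leaves into exactly the members of S versus everything else.  This
reading is rooting-invariant, which is what makes the criterion well-defined
on NJ output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io import BarcodeLibrary

__all__ = ["Tree", "nj_tree", "monospecific_clades", "NjtScore"]

_Q_TIE_TOL = 1e-10


class Tree:
    """Unrooted tree with branch lengths over named leaves.

    Stored as an adjacency map ``node -> {neighbour: branch_length}``; leaf
    nodes carry labels.  Internal nodes of NJ output have degree 3.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}

    def _add_edge(self, a: int, b: int, length: float) -> None:
        self.adj.setdefault(a, {})[b] = length
        self.adj.setdefault(b, {})[a] = length

    @property
    def leaf_names(self) -> set[str]:
        return set(self.labels.values())

    def bipartition_sides(self) -> list[frozenset[str]]:
        """One leaf-label set per edge (the side away from an arbitrary root)."""
        root = next(n for n in self.adj if n not in self.labels) if len(self.labels) < len(
            self.adj
        ) else next(iter(self.adj))
        sides: list[frozenset[str]] = []
        below: dict[int, frozenset[str]] = {}
        # iterative post-order over the tree rooted at `root`
        stack: list[tuple[int, int | None, bool]] = [(root, None, False)]
        while stack:
            node, parent, done = stack.pop()
            if not done:
                stack.append((node, parent, True))
                for nbr in self.adj[node]:
                    if nbr != parent:
                        stack.append((nbr, node, False))
            else:
                if node in self.labels:
                    below[node] = frozenset([self.labels[node]])
                else:
                    acc: set[str] = set()
                    for nbr in self.adj[node]:
                        if nbr != parent:
                            acc |= below[nbr]
                    below[node] = frozenset(acc)
                if parent is not None:
                    sides.append(below[node])
        return sides

    def newick(self) -> str:
        root = next(n for n in self.adj if n not in self.labels) if len(self.labels) < len(
            self.adj
        ) else next(iter(self.adj))

        def _sub(node: int, parent: int | None) -> str:
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                return self.labels[node]
            inner = ",".join(
                f"{_sub(c, node)}:{self.adj[node][c]:.8f}" for c in children
            )
            return f"({inner})"

        return _sub(root, None) + ";"


def nj_tree(dm: DistanceMatrix, seed: int = 0) -> Tree:
    """Saitou-Nei neighbor joining with seeded random tie breaking.

    All pairwise distances must be defined; ties in the Q criterion within
    1e-10 are broken by a seeded uniform draw, so a fixed seed yields an
    identical tree.  Negative branch-length estimates are kept as computed.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    iu, ju = np.triu_indices(n, k=1)
    nan_mask = np.isnan(dm.d[iu, ju])
    if nan_mask.any():
        bad = [(dm.ids[i], dm.ids[j]) for i, j in zip(iu[nan_mask], ju[nan_mask])][:10]
        raise ValueError(f"undefined distances for pairs (first 10): {bad}")
    rng = np.random.default_rng(seed)
    tree = Tree()
    for i, sid in enumerate(dm.ids):
        tree.adj.setdefault(i, {})
        tree.labels[i] = sid
    nodes = list(range(n))
    D = dm.d.astype(float).copy()
    next_id = n
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ti, tj = np.where(Q <= qmin + _Q_TIE_TOL)
        cand = [(a, b) for a, b in zip(ti, tj) if a < b]
        i, j = cand[int(rng.integers(len(cand)))]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = next_id
        next_id += 1
        tree.adj.setdefault(u, {})
        tree._add_edge(u, nodes[i], li)
        tree._add_edge(u, nodes[j], lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [u]
    a, b, c = nodes
    u = next_id
    tree.adj.setdefault(u, {})
    tree._add_edge(u, a, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    tree._add_edge(u, b, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    tree._add_edge(u, c, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    return tree


@dataclass
class NjtScore:
    """Per-species monophyly flags and the derived per-query success."""

    per_species: dict[str, bool]
    per_query: dict[str, bool]
    proportion_correct: float
    by_order: pd.DataFrame


def monospecific_clades(tree: Tree, lib: BarcodeLibrary) -> NjtScore:
    """Score monospecificity of every species on an unrooted tree.

    A species is monospecific iff its member set is exactly one side of some
    edge bipartition (singleton species trivially are; a species spanning
    every leaf is monophyletic by convention).  Each query inherits its
    species' flag; proportions are reported overall and per order.
    """
    members = {sp: set(ids) for sp, ids in lib.species_members().items()}
    leaves = tree.leaf_names
    lib_ids = set(lib.ids)
    if leaves != lib_ids:
        raise ValueError(
            f"tree/library leaf mismatch: {sorted(leaves ^ lib_ids)[:10]} ..."
        )
    sides = set(tree.bipartition_sides())
    all_leaves = frozenset(lib_ids)
    per_species: dict[str, bool] = {}
    for sp, mem in members.items():
        fs = frozenset(mem)
        if fs == all_leaves:
            per_species[sp] = True
        else:
            per_species[sp] = fs in sides or (all_leaves - fs) in sides
    per_query = {r.seq_id: per_species[r.species] for r in lib.records}
    orders = lib.orders
    flags = np.array([per_query[r.seq_id] for r in lib.records])
    rows = []
    for order in sorted(set(orders)):
        mask = orders == order
        n = int(mask.sum())
        n_correct = int(flags[mask].sum())
        rows.append(
            {
                "criterion": "NJT",
                "order": order,
                "n_queries": n,
                "n_correct": n_correct,
                "proportion_correct": n_correct / n,
            }
        )
    return NjtScore(
        per_species=per_species,
        per_query=per_query,
        proportion_correct=float(flags.mean()),
        by_order=pd.DataFrame(rows),
    )
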