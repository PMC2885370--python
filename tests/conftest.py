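"""Shared fixtures and small independent helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodeid import BarcodeLibrary, BarcodeRecord, DistanceMatrix
from barcodeid.simulate import SimulationParams, generate_library


@pytest.fixture(scope="session")
def separated_lib() -> BarcodeLibrary:
    """Small library with a wide barcoding gap (conspecifics always nearest)."""
    return generate_library(
        SimulationParams(
            n_orders=2,
            genera_per_order=5,
            species_per_genus=3,
            individuals_per_species=3,
            d_intra=0.01,
            d_inter=0.15,
            seed=11,
        )
    )


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree; returns (labels, distance matrix, splits).

    Built by repeatedly subdividing a random edge with a new leaf, so tree
    distances are exactly additive.  ``splits`` is the set of canonical
    non-trivial bipartitions (see :func:`canonical_splits`).
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    adj: dict[int, dict[int, float]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def drop_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    nxt = n_leaves
    center = nxt
    nxt += 1
    for leaf in range(3):
        add_edge(center, leaf, rng.uniform(0.1, 1.0))
    for leaf in range(3, n_leaves):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = nxt
        nxt += 1
        drop_edge(a, b)
        split = rng.uniform(0.25, 0.75) * w
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, rng.uniform(0.1, 1.0))
    # leaf-to-leaf path lengths by BFS from each leaf
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    # true splits: for each internal edge, the leaf set on one side
    all_set = frozenset(labels)
    splits = set()
    for a in adj:
        for b in adj[a]:
            if a < b:
                side = set()
                stack = [(b, a)]
                while stack:
                    node, parent = stack.pop()
                    if node < n_leaves:
                        side.add(labels[node])
                    for nbr in adj[node]:
                        if nbr != parent:
                            stack.append((nbr, node))
                if 1 < len(side) < n_leaves - 1:
                    splits.add(canonicalize_split(frozenset(side), all_set))
    return labels, D, splits


def canonicalize_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if (len(side), sorted(side)) <= (len(other), sorted(other)):
        return side
    return other


def canonical_splits(tree, labels) -> set[frozenset]:
    """Non-trivial splits of a barcodeid Tree in canonical form."""
    all_leaves = frozenset(labels)
    out = set()
    for side in tree.bipartition_sides():
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(canonicalize_split(side, all_leaves))
    return out


def make_labelled_dm(rng: np.random.Generator, n: int, n_species: int | None = None,
                     decimals: int = 2, scale: float = 0.2):
    """Random symmetric distance matrix plus a dummy library with species labels.

    Rounding to ``decimals`` places deliberately creates exact distance ties.
    """
    if n_species is None:
        n_species = max(2, n // 3)
    d = np.round(rng.uniform(0.0, scale, size=(n, n)), decimals)
    d = np.triu(d, k=1)
    d = d + d.T
    ids = [f"q{i}" for i in range(n)]
    sp = [f"Sp{rng.integers(n_species)}" for _ in range(n)]
    records = [
        BarcodeRecord(ids[i], sp[i], "GenusX", f"Order{i % 2}", "ACGT") for i in range(n)
    ]
    lib = BarcodeLibrary(records, 4)
    dm = DistanceMatrix(ids, d, np.full((n, n), 4, dtype=np.int64), min_sites=1)
    return dm, lib
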