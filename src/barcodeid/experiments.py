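"""The three benchmarking experiments driven over a barcode library.

1. **Criterion x order comparison** — identification outcomes are computed
   once by leave-one-out over the full library; the records of each order
   are then randomly partitioned into 3 groups (one per criterion) x 3
   sub-groups, and the proportion of correct matches in each sub-group under
   its group's criterion is one replicate.  The resulting balanced table
   (criterion x order x 3 replicates) feeds the mixed two-way ANOVA.
2. **Mini-barcode length series** — the 658-column frame is cut into three
   non-overlapping thirds (MB1: columns 1-220, MB2: 221-439, MB3: 440-658),
   each center-trimmed to 164, 110, 55 and 22 columns; distances, the BCM
   threshold and the success proportions are recomputed per fragment.
3. **Taxon-coverage series** — reference databases of fixed species counts
   are drawn without replacement (all records of each sampled species kept)
   and re-evaluated from scratch, three replicates per size.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import (
    DEFAULT_MIN_SITES,
    DistanceMatrix,
    bcm_threshold,
    distance_matrix,
)
from .io import BarcodeLibrary, BarcodeRecord
from .matching import CORRECT, evaluate_criterion
from .treeid import monospecific_clades, nj_tree

__all__ = [
    "FRAGMENT_SPANS",
    "make_replicates",
    "slice_fragment",
    "compare_criteria",
    "njt_per_query",
    "run_length_series",
    "run_coverage_series",
    "library_digest",
]

#: 0-based half-open column spans of the three mini-barcodes and the full frame
#: (1-based closed: MB1 1-220, MB2 221-439, MB3 440-658).
FRAGMENT_SPANS: dict[str, tuple[int, int]] = {
    "FULL": (0, 658),
    "MB1": (0, 220),
    "MB2": (220, 439),
    "MB3": (439, 658),
}

MINIBARCODE_LENGTHS = (164, 110, 55, 22)


def library_digest(lib: BarcodeLibrary) -> str:
    h = hashlib.sha256()
    for r in lib.records:
        h.update(f"{r.seq_id}\t{r.species}\t{r.aligned_seq}\n".encode())
    return h.hexdigest()[:16]


def make_replicates(
    lib: BarcodeLibrary, seed: int, n_groups: int = 3, n_subgroups: int = 3
) -> pd.DataFrame:
    """Randomly partition each order's records into groups x sub-groups.

    Cell sizes within an order differ by at most one.  Returns a frame with
    columns ``seq_id``, ``order``, ``group`` (1-based), ``subgroup``
    (1-based).  Identical seeds give identical assignments.
    """
    rng = np.random.default_rng(seed)
    rows = []
    orders = lib.orders
    ids = np.asarray(lib.ids, dtype=object)
    for order in sorted(set(orders)):
        order_ids = ids[orders == order]
        if len(order_ids) < n_groups * n_subgroups:
            raise ValueError(
                f"order {order!r} has {len(order_ids)} records; "
                f"need at least {n_groups * n_subgroups} for a {n_groups}x{n_subgroups} design"
            )
        perm = rng.permutation(order_ids)
        for g, group_ids in enumerate(np.array_split(perm, n_groups), start=1):
            for s, cell_ids in enumerate(np.array_split(group_ids, n_subgroups), start=1):
                for sid in cell_ids:
                    rows.append({"seq_id": sid, "order": order, "group": g, "subgroup": s})
    return pd.DataFrame(rows)


def slice_fragment(
    lib: BarcodeLibrary, fragment: str, target_length: int | None = None
) -> BarcodeLibrary:
    """Center-trim one mini-barcode (or the full frame) to ``target_length``.

    The excess over the target is removed symmetrically, with the extra
    column taken from the 3' end when odd.  Taxonomic labels are preserved;
    only columns change.
    """
    if fragment not in FRAGMENT_SPANS:
        raise ValueError(f"unknown fragment {fragment!r}; expected one of {list(FRAGMENT_SPANS)}")
    start, stop = FRAGMENT_SPANS[fragment]
    stop = min(stop, lib.frame_width)
    span = stop - start
    if target_length is None:
        target_length = span
    if target_length > span:
        raise ValueError(f"target length {target_length} exceeds fragment span {span}")
    excess = span - target_length
    start += excess // 2
    stop -= excess - excess // 2
    records = [
        BarcodeRecord(r.seq_id, r.species, r.genus, r.order, r.aligned_seq[start:stop])
        for r in lib.records
    ]
    return BarcodeLibrary(records, target_length)


def _prune_undefined(dm: DistanceMatrix, indices: list[int]) -> list[int]:
    """Greedily drop the index with most undefined pairs until none remain."""
    idx = list(indices)
    sub = dm.d[np.ix_(idx, idx)]
    while True:
        nan_counts = np.isnan(sub).sum(axis=1)
        if nan_counts.sum() == 0:
            return idx
        worst = int(np.argmax(nan_counts))
        del idx[worst]
        sub = np.delete(np.delete(sub, worst, axis=0), worst, axis=1)


def njt_per_query(
    lib: BarcodeLibrary,
    dm: DistanceMatrix,
    seed: int = 0,
    per_order: bool = False,
    max_taxa: int | None = None,
) -> dict[str, bool]:
    """NJT success flag per query, optionally from one tree per order.

    Records involved in undefined distance pairs are pruned before tree
    building and are absent from the returned mapping (they leave the
    denominator).  ``max_taxa`` guards against accidentally requesting an
    O(n^3) tree over a huge library.
    """
    flags: dict[str, bool] = {}
    scopes: list[np.ndarray]
    orders = lib.orders
    if per_order:
        scopes = [np.where(orders == o)[0] for o in sorted(set(orders))]
    else:
        scopes = [np.arange(len(lib))]
    for scope in scopes:
        idx = _prune_undefined(dm, list(scope))
        if len(idx) < 3:
            continue
        if max_taxa is not None and len(idx) > max_taxa:
            raise ValueError(
                f"{len(idx)} taxa exceeds max_taxa={max_taxa}; use per_order=True or raise the guard"
            )
        ids = [dm.ids[i] for i in idx]
        sub_dm = DistanceMatrix(
            ids, dm.d[np.ix_(idx, idx)], dm.n_sites[np.ix_(idx, idx)], dm.min_sites
        )
        sub_lib = lib.subset(ids)
        tree = nj_tree(sub_dm, seed=seed)
        score = monospecific_clades(tree, sub_lib)
        flags.update(score.per_query)
    return flags


def _per_query_correct(
    lib: BarcodeLibrary,
    dm: DistanceMatrix,
    criterion: str,
    threshold: float | None,
    seed: int,
    per_order_trees: bool,
) -> dict[str, bool]:
    """Map query -> correct flag; dropped/pruned queries are absent."""
    if criterion == "NJT":
        return njt_per_query(lib, dm, seed=seed, per_order=per_order_trees)
    res = evaluate_criterion(lib, dm, criterion, threshold=threshold)
    kept = res[res["outcome"] != "dropped"]
    return dict(zip(kept["query_id"], kept["outcome"] == CORRECT))


def compare_criteria(
    lib: BarcodeLibrary,
    criteria: tuple[str, ...] = ("BM", "BCM", "NJT"),
    seed: int = 0,
    dm: DistanceMatrix | None = None,
    threshold: float | None = None,
    per_order_trees: bool = True,
) -> pd.DataFrame:
    """Replicated criterion x order success table (3 replicates per cell).

    Outcomes are evaluated once over the full library; the random 3 x 3
    partition of each order's records assigns each query to exactly one
    (criterion group, sub-group) cell, and each cell's proportion of correct
    matches is one replicate.  The BCM threshold defaults to the library's
    intraspecific 95th percentile.
    """
    if dm is None:
        dm = distance_matrix(lib)
    if threshold is None and "BCM" in criteria:
        threshold = bcm_threshold(dm, lib)
    design = make_replicates(lib, seed, n_groups=len(criteria))
    correct = {
        c: _per_query_correct(lib, dm, c, threshold, seed, per_order_trees) for c in criteria
    }
    rows = []
    for (order, g, s), cell in design.groupby(["order", "group", "subgroup"]):
        crit = criteria[g - 1]
        flags = [correct[crit][sid] for sid in cell["seq_id"] if sid in correct[crit]]
        n = len(flags)
        rows.append(
            {
                "criterion": crit,
                "order": order,
                "replicate": s,
                "n_queries": n,
                "n_correct": int(sum(flags)),
                "proportion_correct": sum(flags) / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["criterion", "order", "replicate"], ignore_index=True)


def _order_proportions(correct: dict[str, bool], lib: BarcodeLibrary) -> list[dict]:
    orders = {r.seq_id: r.order for r in lib.records}
    rows = []
    frame = pd.DataFrame(
        {"order": [orders[q] for q in correct], "ok": list(correct.values())}
    )
    for order, sub in frame.groupby("order"):
        rows.append(
            {
                "order": order,
                "n_queries": len(sub),
                "n_correct": int(sub["ok"].sum()),
                "proportion_correct": float(sub["ok"].mean()),
            }
        )
    return rows


def run_length_series(
    lib: BarcodeLibrary,
    criteria: tuple[str, ...] = ("BM", "BCM", "NJT"),
    seed: int = 0,
    lengths: tuple[int, ...] = MINIBARCODE_LENGTHS,
    fragments: tuple[str, ...] = ("MB1", "MB2", "MB3"),
    min_sites: int = DEFAULT_MIN_SITES,
    per_order_trees: bool = True,
) -> pd.DataFrame:
    """Success proportions across mini-barcode fragments and lengths.

    For every fragment x length the distance matrix and the BCM threshold
    are recomputed on the sliced alignment; the minimum compared-site rule
    scales down with the frame (``min(min_sites, width // 2)``) so that very
    short fragments remain evaluable.  The full-barcode condition is
    reported once per criterion as fragment ``FULL`` at length 658.
    """
    conditions: list[tuple[str, int | None]] = [("FULL", None)]
    for frag in fragments:
        span = FRAGMENT_SPANS[frag][1] - FRAGMENT_SPANS[frag][0]
        conditions.append((frag, None))
        conditions.extend((frag, L) for L in lengths if L < span)
    rows = []
    for frag, L in conditions:
        slib = slice_fragment(lib, frag, L)
        ms = min(min_sites, max(1, slib.frame_width // 2))
        dm = distance_matrix(slib, min_sites=ms)
        thr = bcm_threshold(dm, slib) if "BCM" in criteria else None
        x = 658 if frag == "FULL" else (L if L is not None else slib.frame_width)
        for crit in criteria:
            correct = _per_query_correct(slib, dm, crit, thr, seed, per_order_trees)
            for row in _order_proportions(correct, slib):
                rows.append({"criterion": crit, "fragment": frag, "length": x, **row})
    return pd.DataFrame(rows)


def run_coverage_series(
    lib: BarcodeLibrary,
    sizes: tuple[int, ...],
    n_replicates: int = 3,
    seed: int = 0,
    criteria: tuple[str, ...] = ("BM", "BCM"),
    min_sites: int = DEFAULT_MIN_SITES,
    include_full: bool = True,
) -> pd.DataFrame:
    """Identification success versus species coverage of the reference database.

    For each size x replicate a species subset is sampled without
    replacement, all records of the sampled species are retained, and each
    criterion is re-evaluated from scratch inside that subsample (the BCM
    threshold included) — queries never see sequences outside it.  The
    full-library point is appended at size = total species count.
    """
    all_species = sorted(set(r.species for r in lib.records))
    if max(sizes) > len(all_species):
        raise ValueError(f"requested {max(sizes)} species but library has {len(all_species)}")
    rng = np.random.default_rng(seed)
    rows = []

    def _evaluate(sub: BarcodeLibrary, size: int, replicate: int) -> None:
        dm = distance_matrix(sub, min_sites=min_sites)
        thr = bcm_threshold(dm, sub) if "BCM" in criteria else None
        for crit in criteria:
            correct = _per_query_correct(sub, dm, crit, thr, seed, True)
            n = len(correct)
            rows.append(
                {
                    "criterion": crit,
                    "n_species": size,
                    "replicate": replicate,
                    "n_queries": n,
                    "n_correct": int(sum(correct.values())),
                    "proportion_correct": sum(correct.values()) / n if n else math.nan,
                }
            )

    for size in sizes:
        for rep in range(1, n_replicates + 1):
            chosen = rng.choice(all_species, size=size, replace=False)
            _evaluate(lib.subset(
                r.seq_id for r in lib.records if r.species in set(chosen)
            ), size, rep)
    if include_full:
        _evaluate(lib, len(all_species), 0)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, lib: BarcodeLibrary, **params) -> None:
    """Sidecar manifest making an experiment table re-derivable."""
    payload = {
        "library_digest": library_digest(lib),
        "n_records": len(lib),
        "n_species": lib.n_species,
        **params,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
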