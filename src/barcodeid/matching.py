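"""Distance-based identification criteria under leave-one-out evaluation.

Three criteria, in increasing strictness:

* **Best match (BM)** — the query takes the species of its nearest reference
  sequence, unconditionally.
* **Best close match (BCM)** — as BM, but only when the best distance lies
  strictly below a threshold (conventionally the 95th percentile of
  intraspecific distances); otherwise no identification.
* **All species barcodes (ASB)** — correct only when *every* conspecific of
  the query outranks every other species in the match list; requires at
  least two conspecific references per query.

Every record serves once as a query against all the others.  Ambiguity
(distance ties spanning species) is preserved in per-query output but scored
as not-correct in success proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io import BarcodeLibrary

__all__ = [
    "IdentificationResult",
    "best_match",
    "best_close_match",
    "all_species_barcodes",
    "evaluate_criterion",
    "success_table",
]

TIE_TOL = 1e-10  # K2P on identical discrete inputs is bit-identical, so real ties are exact

CORRECT = "correct"
INCORRECT = "incorrect"
AMBIGUOUS = "ambiguous"
NO_ID = "no_id"


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of one query under one criterion."""

    query_id: str
    criterion: str
    outcome: str
    best_match_ids: tuple[str, ...] = ()
    best_distance: float = math.nan


def _query_distances(dm: DistanceMatrix, query_id: str) -> np.ndarray:
    qi = dm.index_of(query_id)
    d = dm.d[qi].astype(float).copy()
    d[qi] = np.nan  # self excluded
    return d


def _bm_outcome(d: np.ndarray, species: np.ndarray, q_species: str, ids: list[str]):
    if np.all(np.isnan(d)):
        raise ValueError("no defined distances for this query")
    dmin = np.nanmin(d)
    tied = np.where(d <= dmin + TIE_TOL)[0]
    tied_species = set(species[tied])
    if tied_species == {q_species}:
        outcome = CORRECT
    elif q_species in tied_species:
        outcome = AMBIGUOUS
    else:
        outcome = INCORRECT
    return outcome, tuple(ids[i] for i in tied), float(dmin)


def best_match(query_id: str, dm: DistanceMatrix, lib: BarcodeLibrary) -> IdentificationResult:
    """Best-match identification: nearest reference wins, ties spanning species are ambiguous."""
    q = lib.records[dm.index_of(query_id)]
    d = _query_distances(dm, query_id)
    outcome, tied_ids, dmin = _bm_outcome(d, lib.species, q.species, dm.ids)
    return IdentificationResult(query_id, "BM", outcome, tied_ids, dmin)


def best_close_match(
    query_id: str, dm: DistanceMatrix, lib: BarcodeLibrary, threshold: float
) -> IdentificationResult:
    """Best close match: as BM but no identification unless best distance < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    r = best_match(query_id, dm, lib)
    outcome = r.outcome if r.best_distance < threshold else NO_ID
    return IdentificationResult(query_id, "BCM", outcome, r.best_match_ids, r.best_distance)


def all_species_barcodes(
    query_id: str, dm: DistanceMatrix, lib: BarcodeLibrary
) -> IdentificationResult:
    """All-species-barcodes: correct only if every conspecific tops the match list.

    The query's species must have at least two conspecific references (the
    dataset-B rule).  Conspecifics whose distance to the query is undefined
    cannot be ranked and are excluded from the requirement.  A tie between
    the worst conspecific and the best other-species record is ambiguous;
    any other failure of the ranking condition is no identification.
    """
    qi = dm.index_of(query_id)
    q_species = lib.records[qi].species
    species = lib.species
    d = _query_distances(dm, query_id)
    cons = (species == q_species) & (np.arange(len(d)) != qi)
    if cons.sum() < 2:
        raise ValueError(
            f"query {query_id!r}: species {q_species!r} has fewer than 2 other records; "
            "apply build_dataset(lib, min_conspecifics=2) first"
        )
    d_cons = d[cons]
    d_allo = d[~cons & ~np.isnan(d)]
    d_cons_def = d_cons[~np.isnan(d_cons)]
    if d_cons_def.size == 0:
        raise ValueError(f"query {query_id!r}: no defined conspecific distances")
    dmin = float(np.nanmin(d))
    tied = np.where(d <= dmin + TIE_TOL)[0]
    worst_cons = float(d_cons_def.max())
    if d_allo.size == 0:
        outcome = CORRECT
    else:
        best_allo = float(d_allo.min())
        if worst_cons < best_allo - TIE_TOL:
            outcome = CORRECT
        elif worst_cons <= best_allo + TIE_TOL:
            outcome = AMBIGUOUS
        else:
            outcome = NO_ID
    return IdentificationResult(
        query_id, "ASB", outcome, tuple(dm.ids[i] for i in tied), dmin
    )


def evaluate_criterion(
    lib: BarcodeLibrary,
    dm: DistanceMatrix,
    criterion: str,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Leave-one-out evaluation of one criterion over a whole library.

    Returns the per-query result table (``query_id``, ``species``, ``order``,
    ``criterion``, ``outcome``, ``best_match_ids``, ``best_distance``).
    Queries with no defined candidate distance are recorded with outcome
    ``dropped`` and excluded from success denominators downstream.
    """
    criterion = criterion.upper()
    if criterion == "BCM" and threshold is None:
        raise ValueError("BCM requires a threshold (use bcm_threshold)")
    rows = []
    for rec in lib.records:
        try:
            if criterion == "BM":
                r = best_match(rec.seq_id, dm, lib)
            elif criterion == "BCM":
                r = best_close_match(rec.seq_id, dm, lib, threshold)
            elif criterion == "ASB":
                r = all_species_barcodes(rec.seq_id, dm, lib)
            else:
                raise ValueError(f"unknown distance criterion {criterion!r}")
        except ValueError as err:
            if "fewer than 2 other records" in str(err):
                raise
            r = IdentificationResult(rec.seq_id, criterion, "dropped")
        rows.append(
            {
                "query_id": rec.seq_id,
                "species": rec.species,
                "order": rec.order,
                "criterion": criterion,
                "outcome": r.outcome,
                "best_match_ids": ",".join(r.best_match_ids),
                "best_distance": r.best_distance,
            }
        )
    return pd.DataFrame(rows)


def success_table(results: pd.DataFrame, by: str = "order") -> pd.DataFrame:
    """Aggregate per-query outcomes into proportions of correct matches.

    Only ``correct`` counts as a success; ``ambiguous``, ``incorrect`` and
    ``no_id`` all count against.  ``dropped`` queries leave the denominator.
    """
    kept = results[results["outcome"] != "dropped"]
    grouped = kept.groupby(["criterion", by], sort=True)
    rows = []
    for (crit, group), sub in grouped:
        n = len(sub)
        n_correct = int((sub["outcome"] == CORRECT).sum())
        rows.append(
            {
                "criterion": crit,
                by: group,
                "n_queries": n,
                "n_correct": n_correct,
                "proportion_correct": n_correct / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows)
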