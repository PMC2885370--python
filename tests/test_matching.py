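"""Identification criteria: spec'd outcomes, ties, thresholds, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeid import (
    all_species_barcodes,
    best_close_match,
    best_match,
    evaluate_criterion,
    success_table,
)
from barcodeid.matching import AMBIGUOUS, CORRECT, INCORRECT, NO_ID

from conftest import make_labelled_dm


def _dm_lib(distances, species):
    """Tiny labelled matrix from {(i, j): d} over len(species) records."""
    import numpy as np

    from barcodeid import BarcodeLibrary, BarcodeRecord, DistanceMatrix

    n = len(species)
    d = np.zeros((n, n))
    for (i, j), v in distances.items():
        d[i, j] = d[j, i] = v
    ids = [f"s{i + 1}" for i in range(n)]
    recs = [BarcodeRecord(ids[i], species[i], "G", "Ord", "ACGT") for i in range(n)]
    return DistanceMatrix(ids, d, np.full((n, n), 4, np.int64), 1), BarcodeLibrary(recs, 4)


def test_best_match_unique_tied_and_allospecific_minima():
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.05, (1, 2): 0.04}, ["A", "A", "B"])
    assert best_match("s1", dm, lib).outcome == CORRECT
    dm, lib = _dm_lib({(0, 1): 0.02, (0, 2): 0.02, (1, 2): 0.04}, ["A", "A", "B"])
    r = best_match("s1", dm, lib)
    assert r.outcome == AMBIGUOUS and set(r.best_match_ids) == {"s2", "s3"}
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.05, (1, 2): 0.04}, ["A", "B", "A"])
    assert best_match("s1", dm, lib).outcome == INCORRECT


def test_best_close_match_threshold_is_strictly_below():
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.05, (1, 2): 0.04}, ["A", "A", "B"])
    assert best_close_match("s1", dm, lib, 0.0764).outcome == CORRECT
    dm, lib = _dm_lib({(0, 1): 0.10, (0, 2): 0.15, (1, 2): 0.04}, ["A", "A", "B"])
    assert best_close_match("s1", dm, lib, 0.0764).outcome == NO_ID
    # exactly at the threshold: "below" is strict, so no identification
    dm, lib = _dm_lib({(0, 1): 0.0764, (0, 2): 0.15, (1, 2): 0.04}, ["A", "A", "B"])
    assert best_close_match("s1", dm, lib, 0.0764).outcome == NO_ID


def test_all_species_barcodes_ranking_rule():
    sp = ["A", "A", "A", "B"]
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.02, (0, 3): 0.05}, sp)
    assert all_species_barcodes("s1", dm, lib).outcome == CORRECT
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.06, (0, 3): 0.05}, sp)
    assert all_species_barcodes("s1", dm, lib).outcome == NO_ID
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.05, (0, 3): 0.05}, sp)
    assert all_species_barcodes("s1", dm, lib).outcome == AMBIGUOUS


def test_asb_requires_two_conspecifics():
    dm, lib = _dm_lib({(0, 1): 0.01, (0, 2): 0.05}, ["A", "A", "B"])
    with pytest.raises(ValueError, match="min_conspecifics=2"):
        all_species_barcodes("s1", dm, lib)


def test_asb_success_implies_bm_success():
    rng = np.random.default_rng(5)
    for _ in range(50):
        dm, lib = make_labelled_dm(rng, int(rng.integers(6, 25)))
        counts = {sp: len(v) for sp, v in lib.species_members().items()}
        for rec in lib.records:
            if counts[rec.species] < 3:
                continue
            asb = all_species_barcodes(rec.seq_id, dm, lib)
            if asb.outcome == CORRECT:
                assert best_match(rec.seq_id, dm, lib).outcome == CORRECT


def test_bcm_with_infinite_threshold_equals_bm():
    rng = np.random.default_rng(9)
    for _ in range(30):
        dm, lib = make_labelled_dm(rng, int(rng.integers(4, 20)))
        for rec in lib.records:
            bm = best_match(rec.seq_id, dm, lib)
            bcm = best_close_match(rec.seq_id, dm, lib, math.inf)
            assert bm.outcome == bcm.outcome
            assert bm.best_match_ids == bcm.best_match_ids


def test_evaluate_criterion_scores_only_correct():
    dm, lib = _dm_lib(
        {(0, 1): 0.0, (0, 2): 0.3, (0, 3): 0.3, (1, 2): 0.3, (1, 3): 0.3, (2, 3): 0.0},
        ["A", "A", "B", "B"],
    )
    res = evaluate_criterion(lib, dm, "BM")
    table = success_table(res)
    assert table["proportion_correct"].tolist() == [1.0]
    assert (table["n_queries"] == [4]).all()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_bm_outcome_matches_bruteforce_sort(seed):
    """BM/BCM outcomes agree with an explicit candidate sort on tied matrices."""
    rng = np.random.default_rng(seed)
    dm, lib = make_labelled_dm(rng, int(rng.integers(4, 30)))
    species = lib.species
    thr = 0.1
    for qi, rec in enumerate(lib.records):
        cand = [(dm.d[qi, j], j) for j in range(len(lib)) if j != qi]
        dmin = min(c[0] for c in cand)
        tied_sp = {species[j] for dv, j in cand if dv == dmin}
        expect = (
            CORRECT if tied_sp == {rec.species}
            else AMBIGUOUS if rec.species in tied_sp
            else INCORRECT
        )
        assert best_match(rec.seq_id, dm, lib).outcome == expect
        expect_bcm = expect if dmin < thr else NO_ID
        assert best_close_match(rec.seq_id, dm, lib, thr).outcome == expect_bcm
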