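"""K2P arithmetic, matrix construction and barcoding-gap summaries."""

import math

import numpy as np
import pytest

from barcodeid import (
    BarcodeLibrary,
    BarcodeRecord,
    bcm_threshold,
    distance_matrix,
    k2p,
    summarize_distances,
)

# closed-form K2P values for 4-site pairs (d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q))
ONE_TRANSITION = -0.5 * math.log(0.5)  # P=1/4, Q=0
ONE_TRANSVERSION = -0.5 * math.log(0.75) - 0.25 * math.log(0.5)  # P=0, Q=1/4


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "GCGT", ONE_TRANSITION),  # A->G transition
        ("ACGT", "CCGT", ONE_TRANSVERSION),  # A->C transversion
    ],
)
def test_k2p_matches_closed_form(a, b, expected):
    d, n = k2p(a, b)
    assert n == 4
    assert d == pytest.approx(expected, abs=1e-12)


def test_k2p_pairwise_deletion_and_min_sites():
    d, n = k2p("ACGTNN-R", "ACGAACGT")
    assert n == 4  # N, '-' and ambiguity codes drop the column
    d2, n2 = k2p("ACGT", "ACGT", min_sites=5)
    assert math.isnan(d2) and n2 == 4


def test_k2p_saturation_is_flagged_not_clamped():
    # every site a transversion: Q = 1 -> both log arguments <= 0
    d, n = k2p("AAAA", "CCCC")
    assert math.isnan(d) and n == 4


def test_k2p_frame_width_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        k2p("ACGT", "ACG")


def test_equal_counts_transitions_imply_larger_distance():
    """Transitions saturate faster under K2P, so at an equal observed
    proportion the transition-only distance exceeds the transversion-only
    one: -1/2 ln(1-2x) > -1/2 ln(1-x) - 1/4 ln(1-2x) for x in (0, 1/4)."""
    for x in np.linspace(0.01, 0.24, 24):
        d_ts = -0.5 * math.log(1 - 2 * x)
        d_tv = -0.5 * math.log(1 - x) - 0.25 * math.log(1 - 2 * x)
        assert d_ts > d_tv


def _lib_from_seqs(seqs, species=None, genus=None):
    n = len(seqs)
    species = species or [f"Sp{i}" for i in range(n)]
    genus = genus or ["G"] * n
    recs = [
        BarcodeRecord(f"s{i}", species[i], genus[i], "Ord", seqs[i]) for i in range(n)
    ]
    return BarcodeLibrary(recs, len(seqs[0]))


def test_distance_matrix_equals_scalar_k2p():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(3, 15))
        seqs = [
            "".join(rng.choice(list("ACGTN"), 60, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            for _ in range(n)
        ]
        lib = _lib_from_seqs(seqs)
        dm = distance_matrix(lib, min_sites=5)
        assert np.array_equal(dm.d, dm.d.T) or np.allclose(dm.d, dm.d.T, equal_nan=True)
        for i in range(n):
            for j in range(i + 1, n):
                d, ns = k2p(seqs[i], seqs[j], min_sites=5)
                assert dm.n_sites[i, j] == ns
                if math.isnan(d):
                    assert math.isnan(dm.d[i, j])
                else:
                    assert dm.d[i, j] == pytest.approx(d, abs=1e-12)


def test_identical_sequences_give_zero_matrix():
    lib = _lib_from_seqs(["ACGTACGT"] * 3)
    dm = distance_matrix(lib, min_sites=1)
    assert np.all(dm.d == 0.0)


def test_disjoint_distributions_have_zero_overlap():
    # two species per genus; conspecifics identical, congeners far apart
    # (differences are transversions so the K2P correction stays defined)
    seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AACCAAAAAA", "AACCAAAAAA"]
    lib = _lib_from_seqs(seqs, species=["A x", "A x", "A y", "A y"], genus=["A"] * 4)
    dm = distance_matrix(lib, min_sites=1)
    s = summarize_distances(dm, lib)
    assert s.overlap_fraction == 0.0
    assert np.all(s.intraspecific == 0.0)
    assert np.all(s.interspecific_congeneric > 0.1)


def test_congeneric_summary_uses_per_species_pair_means():
    seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AAGAAAAAAA", "CCTTAAAAAA"]
    lib = _lib_from_seqs(
        seqs, species=["A x", "A x", "A y", "A z"], genus=["A"] * 4
    )
    dm = distance_matrix(lib, min_sites=1)
    s = summarize_distances(dm, lib)
    # three species pairs (x,y), (x,z), (y,z); pair (x,y) averages two sequence pairs
    assert s.interspecific_congeneric.size == 3
    assert s.interspecific_congeneric_raw.size == 5


def test_bcm_threshold_percentile_convention():
    """95th percentile with linear interpolation between order statistics."""
    vals = np.arange(100) / 100.0  # 0.00, 0.01, ..., 0.99
    assert np.percentile(vals, 95) == pytest.approx(0.9405)
    # degenerate distribution: threshold equals the common value
    lib = _lib_from_seqs(
        ["AACGTACGTA", "AGCGTACGTA", "TACGTACGTA", "TGCGTACGTA"],
        species=["A x", "A x", "A y", "A y"],
        genus=["A"] * 4,
    )
    dm = distance_matrix(lib, min_sites=1)
    d_intra = dm.d[0, 1]
    assert bcm_threshold(dm, lib) == pytest.approx(d_intra)
    with pytest.raises(ValueError):
        bcm_threshold(dm, lib, quantile=1.5)


def test_threshold_requires_intraspecific_pairs():
    lib = _lib_from_seqs(["ACGTACGTAC", "AGGTACGTAC"])  # two singleton species
    dm = distance_matrix(lib, min_sites=1)
    with pytest.raises(ValueError, match="intraspecific"):
        bcm_threshold(dm, lib)
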