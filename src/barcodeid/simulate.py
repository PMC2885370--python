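"""Synthetic aligned barcode libraries with controlled divergence structure.

The generator emulates the shape of a curated COI reference library: a
hierarchy of orders > genera > species > individuals, a fixed 658-column
alignment frame, and ragged record ends (550-658 determined bases).  Sequence
evolution follows the Kimura 1980 (K80) two-parameter model, the model whose
distance estimator (K2P) the downstream analysis uses, so the generator's
``d_intra`` and ``d_inter`` dials are on the same scale as the measured
distances.

Topology is deliberately minimal: a star phylogeny at every level.  A
uniform-random root sequence spawns order ancestors (branch ``d_order/2``),
each order ancestor spawns genus ancestors (branch ``d_genus/2``), each
genus ancestor spawns species ancestors (branch ``(d_inter - d_intra)/2``,
clamped at zero), and each species ancestor spawns individuals (branch
``d_intra/2``).  Because paths add, the *measured* expectations come out on
the dials: conspecific individuals at K2P ``d_intra`` and congeneric
individuals at ``d_inter`` (the species-branch offset absorbs the
individual branches), which is what makes the overlap of the two
distributions directly controllable.  Keeping the upper levels on finite
branches rather than drawing ancestors independently keeps even
between-order pairs below K2P saturation, so complete distance matrices
and global NJ trees exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import BarcodeLibrary, BarcodeRecord

__all__ = ["SimulationParams", "mutate_sequence", "generate_library"]

_BASES = "AGCT"  # index order matches the A=0, G=1, C=2, T=3 encoding


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic library.

    Defaults describe a moderately sized, dataset-B-qualified insect library
    (6 orders x 10 genera x 3 species x 3 individuals = 540 records over 180
    species) in the overlapping-distributions regime typical of dense COI
    libraries: expected intraspecific K2P 0.02, expected congeneric
    interspecific K2P 0.10, between-genus and between-order ancestor
    divergences 0.20 each, transition/transversion rate ratio 3.
    """

    n_orders: int = 6
    genera_per_order: int = 10
    species_per_genus: int | tuple[int, int] = 3
    individuals_per_species: int = 3
    alignment_length: int = 658
    d_intra: float = 0.02
    d_inter: float = 0.10
    d_genus: float = 0.20
    d_order: float = 0.20
    kappa: float = 3.0
    ragged_min_length: int = 550
    seed: int = 0

    def validate(self) -> None:
        if self.n_orders < 1 or self.genera_per_order < 1:
            raise ValueError("n_orders and genera_per_order must be >= 1")
        lo, hi = self._species_range()
        if lo < 1:
            raise ValueError("species_per_genus must be >= 1")
        if hi < lo:
            raise ValueError("species_per_genus range must be (lo, hi) with lo <= hi")
        if self.individuals_per_species < 2:
            raise ValueError("individuals_per_species must be >= 2")
        if min(self.d_intra, self.d_inter, self.d_genus, self.d_order) < 0:
            raise ValueError("divergence parameters must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.ragged_min_length <= self.alignment_length):
            raise ValueError("need 0 < ragged_min_length <= alignment_length")

    def _species_range(self) -> tuple[int, int]:
        if isinstance(self.species_per_genus, tuple):
            return self.species_per_genus
        return (self.species_per_genus, self.species_per_genus)


def _k80_site_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(one specific transversion)) after branch length d.

    The K80 rate matrix is scaled so that the branch length is the expected
    number of substitutions per site: alpha = kappa/(kappa+2), beta =
    1/(kappa+2).  At these probabilities the plug-in K2P estimate of the
    input/output divergence equals d exactly.
    """
    e1 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def mutate_sequence(
    seq: str | np.ndarray,
    branch_distance: float,
    kappa: float,
    rng: np.random.Generator,
) -> str | np.ndarray:
    """Evolve a sequence along one branch under the K80 model.

    ``branch_distance`` is in expected substitutions per site; transitions
    occur ``kappa`` times more often than each transversion type.  Accepts a
    nucleotide string or a uint8 code vector (A=0, G=1, C=2, T=3) and returns
    the same type.
    """
    if branch_distance < 0:
        raise ValueError("branch_distance must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    as_str = isinstance(seq, str)
    codes = np.frombuffer(seq.encode(), np.uint8) if as_str else np.asarray(seq, np.uint8)
    if as_str:
        lut = np.zeros(256, np.uint8)
        for i, b in enumerate(_BASES):
            lut[ord(b)] = i
        codes = lut[codes]
    p_ts, p_tv = _k80_site_probabilities(branch_distance, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    # encoding makes mutation a XOR: ^1 = transition partner, ^2/^3 = transversions
    out[u < p_ts] ^= 1
    out[(u >= p_ts) & (u < p_ts + p_tv)] ^= 2
    out[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] ^= 3
    if as_str:
        return "".join(_BASES[c] for c in out)
    return out


def _decode(codes: np.ndarray) -> list[str]:
    return [_BASES[c] for c in codes]


def generate_library(params: SimulationParams) -> BarcodeLibrary:
    """Generate one aligned barcode library under the star-phylogeny model.

    Every species has exactly ``individuals_per_species`` records.  Each
    record's determined span is a contiguous block of uniform length in
    ``[ragged_min_length, alignment_length]`` at a uniform offset; frame
    columns outside it are 'N' ('-' is reserved for true indels, which are
    never generated).  Identical parameters (including seed) give
    byte-identical libraries.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.alignment_length
    sp_lo, sp_hi = params._species_range()
    records: list[BarcodeRecord] = []
    root = rng.integers(0, 4, size=L).astype(np.uint8)
    for o in range(params.n_orders):
        order = f"Order{o + 1:02d}"
        order_anc = mutate_sequence(root, params.d_order / 2.0, params.kappa, rng)
        for g in range(params.genera_per_order):
            genus = f"Genus{o + 1:02d}{g + 1:02d}"
            genus_anc = mutate_sequence(order_anc, params.d_genus / 2.0, params.kappa, rng)
            n_species = int(rng.integers(sp_lo, sp_hi + 1)) if sp_hi > sp_lo else sp_lo
            sp_branch = max(params.d_inter - params.d_intra, 0.0) / 2.0
            for s in range(n_species):
                species = f"{genus} species{s + 1:02d}"
                sp_anc = mutate_sequence(genus_anc, sp_branch, params.kappa, rng)
                for i in range(params.individuals_per_species):
                    codes = mutate_sequence(sp_anc, params.d_intra / 2.0, params.kappa, rng)
                    length = int(rng.integers(params.ragged_min_length, L + 1))
                    start = int(rng.integers(0, L - length + 1))
                    chars = _decode(codes)
                    seq = "N" * start + "".join(chars[start : start + length]) + "N" * (
                        L - start - length
                    )
                    records.append(
                        BarcodeRecord(
                            seq_id=f"O{o + 1:02d}G{g + 1:02d}S{s + 1:02d}I{i + 1:02d}",
                            species=species,
                            genus=genus,
                            order=order,
                            aligned_seq=seq,
                        )
                    )
    return BarcodeLibrary(records, L)
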