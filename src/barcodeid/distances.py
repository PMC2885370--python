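"""Kimura 2-parameter distances and barcoding-gap summaries.

K2P corrects observed divergence separately for transitions (proportion P)
and transversions (Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence holds anything but an unambiguous A/C/G/T are
excluded pair by pair (pairwise deletion), which is what ragged 550-658 bp
records require.  A pair is *undefined* — NaN, never silently zero — when
fewer than ``min_sites`` columns are comparable or when a log argument is
non-positive (saturation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BarcodeLibrary, encode_sequence

__all__ = [
    "DistanceMatrix",
    "DistanceSummary",
    "k2p",
    "distance_matrix",
    "summarize_distances",
    "bcm_threshold",
]

DEFAULT_MIN_SITES = 100


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair compared-site counts.

    ``d`` holds NaN for undefined pairs; ``n_sites[i, j]`` is the number of
    columns where both sequences held an unambiguous base.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    min_sites: int = DEFAULT_MIN_SITES

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shapes must match the id list")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, seq_id: str) -> int:
        return self._index[seq_id]

    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        mask = np.isnan(self.d[iu, ju])
        return [(self.ids[i], self.ids[j]) for i, j in zip(iu[mask], ju[mask])]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.ids)), 2):
            rows.append((self.ids[i], self.ids[j], self.d[i, j], int(self.n_sites[i, j])))
        return pd.DataFrame(rows, columns=["id1", "id2", "k2p", "n_sites"])

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP matrix; undefined entries written as -1.0."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                vals = " ".join(
                    f"{(-1.0 if np.isnan(v) else v):.6f}" for v in self.d[i]
                )
                fh.write(f"{sid}  {vals}\n")


def _k2p_from_counts(ts: np.ndarray, tv: np.ndarray, n: np.ndarray, min_sites: int):
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n > 0, ts / np.maximum(n, 1), np.nan)
        Q = np.where(n > 0, tv / np.maximum(n, 1), np.nan)
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    bad = (n < min_sites) | (a1 <= 0) | (a2 <= 0)
    return np.where(bad, np.nan, d)


def k2p(seq_a: str, seq_b: str, min_sites: int = 1) -> tuple[float, int]:
    """K2P distance and compared-site count for one aligned pair.

    Returns ``(nan, n)`` when fewer than ``min_sites`` sites are comparable
    or the correction saturates.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"frame width mismatch: {len(seq_a)} vs {len(seq_b)}")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    valid = (a != 255) & (b != 255)
    n = int(valid.sum())
    av, bv = a[valid], b[valid]
    diff = av != bv
    # A=0/G=1 and C=2/T=3 share the high bit, so a transition flips only bit 0
    ts = int((diff & ((av >> 1) == (bv >> 1))).sum())
    tv = int(diff.sum()) - ts
    d = _k2p_from_counts(np.array(ts, float), np.array(tv, float), np.array(n, float), min_sites)
    return float(d), n


def distance_matrix(lib: BarcodeLibrary, min_sites: int = DEFAULT_MIN_SITES) -> DistanceMatrix:
    """All pairwise K2P distances of a library, via one-hot matrix products."""
    if len(lib) < 2:
        raise ValueError("need at least 2 records")
    X = lib.encoded()
    V = (X != 255).astype(np.float32)
    onehot = [(X == b).astype(np.float32) for b in range(4)]
    n = V @ V.T
    ident = sum(h @ h.T for h in onehot)
    ts = onehot[0] @ onehot[1].T + onehot[2] @ onehot[3].T
    ts = ts + ts.T
    tv = n - ident - ts
    d = _k2p_from_counts(ts.astype(float), tv.astype(float), n.astype(float), min_sites)
    np.fill_diagonal(d, 0.0)
    n_sites = np.rint(n).astype(np.int64)
    return DistanceMatrix(list(lib.ids), d, n_sites, min_sites=min_sites)


@dataclass
class DistanceSummary:
    """Barcoding-gap summary of one library's distance structure.

    ``intraspecific`` pools every defined conspecific pairwise distance;
    ``interspecific_congeneric`` holds one mean per pair of distinct
    congeneric species.  ``intra_upper95`` is the 95th percentile of the
    intraspecific distribution (the BCM threshold construction);
    ``inter_central95`` the central [2.5th, 97.5th] band of the congeneric
    means; ``overlap_fraction`` the proportion of pooled values falling
    strictly between the lower interspecific bound and the upper
    intraspecific bound.
    """

    intraspecific: np.ndarray
    interspecific_congeneric: np.ndarray
    interspecific_congeneric_raw: np.ndarray
    intra_upper95: float
    inter_central95: tuple[float, float]
    overlap_fraction: float
    overlap_fraction_intra: float
    overlap_fraction_inter: float


def _pair_values(dm: DistanceMatrix, lib: BarcodeLibrary):
    species = lib.species
    genera = lib.genera
    n = len(lib)
    iu, ju = np.triu_indices(n, k=1)
    d = dm.d[iu, ju]
    same_sp = species[iu] == species[ju]
    same_gen = genera[iu] == genera[ju]
    defined = ~np.isnan(d)
    intra = d[same_sp & defined]
    congen_mask = same_gen & ~same_sp & defined
    congen_raw = d[congen_mask]
    # one mean per unordered pair of distinct congeneric species
    pair_keys = [
        tuple(sorted((species[i], species[j])))
        for i, j in zip(iu[congen_mask], ju[congen_mask])
    ]
    means: dict[tuple[str, str], list[float]] = {}
    for key, val in zip(pair_keys, congen_raw):
        means.setdefault(key, []).append(float(val))
    congen_means = np.array([np.mean(v) for v in means.values()])
    return intra, congen_means, congen_raw


def summarize_distances(dm: DistanceMatrix, lib: BarcodeLibrary) -> DistanceSummary:
    """Intra/interspecific distance distributions and their overlap."""
    intra, congen_means, congen_raw = _pair_values(dm, lib)
    if intra.size == 0 or congen_means.size == 0:
        empty = "intraspecific" if intra.size == 0 else "interspecific congeneric"
        raise ValueError(f"no defined {empty} distances in this library")
    intra_hi = float(np.percentile(intra, 95))
    inter_lo, inter_hi = (float(v) for v in np.percentile(congen_means, [2.5, 97.5]))
    pooled = np.concatenate([intra, congen_means])

    def _frac_inside(values: np.ndarray) -> float:
        if inter_lo >= intra_hi:
            return 0.0
        return float(np.mean((values > inter_lo) & (values < intra_hi)))

    return DistanceSummary(
        intraspecific=intra,
        interspecific_congeneric=congen_means,
        interspecific_congeneric_raw=congen_raw,
        intra_upper95=intra_hi,
        inter_central95=(inter_lo, inter_hi),
        overlap_fraction=_frac_inside(pooled),
        overlap_fraction_intra=_frac_inside(intra),
        overlap_fraction_inter=_frac_inside(congen_means),
    )


def bcm_threshold(dm: DistanceMatrix, lib: BarcodeLibrary, quantile: float = 0.95) -> float:
    """Distance below which ``quantile`` of intraspecific distances fall.

    The 0.95 default is the standard best-close-match threshold; percentiles
    interpolate linearly between order statistics.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    intra, _, _ = _pair_values(dm, lib)
    if intra.size == 0:
        raise ValueError("no defined intraspecific distances; cannot set a threshold")
    return float(np.percentile(intra, 100 * quantile))
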