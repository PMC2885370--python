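"""Reading, writing and filtering aligned barcode libraries.

A barcode library is a set of COI sequences sharing one alignment frame
(typically 658 columns, the Folmer fragment) together with a three-level
taxonomy (order > genus > species).  Real sequence spans 550-658 bp inside
the frame; columns outside a record's span hold 'N', true alignment gaps
hold '-'.  Metadata travels in a sidecar TSV (``seq_id  species  genus
order``); a fallback ``>id|species|genus|order`` FASTA-header convention is
also understood.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "BarcodeLibrary",
    "read_library",
    "write_library",
    "filter_records",
    "build_dataset",
    "OPEN_NOMENCLATURE_PATTERNS",
]

_MISSING = set("N-")

# Character -> code used throughout: A=0, G=1 (purines), C=2, T=3 (pyrimidines);
# everything else (N, -, IUPAC ambiguity codes) -> 255 and is ignored pairwise.
_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _v in (("A", 0), ("G", 1), ("C", 2), ("T", 3)):
    _CODE[ord(_c)] = _v
    _CODE[ord(_c.lower())] = _v


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, G=1, C=2, T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode with its taxonomic labels."""

    seq_id: str
    species: str
    genus: str
    order: str
    aligned_seq: str

    @property
    def real_length(self) -> int:
        """Number of determined positions ('N' and '-' both count as missing)."""
        return sum(1 for c in self.aligned_seq if c not in _MISSING)


@dataclass
class BarcodeLibrary:
    """An ordered collection of records sharing one alignment frame."""

    records: list[BarcodeRecord]
    frame_width: int

    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if len(r.aligned_seq) != self.frame_width:
                raise ValueError(
                    f"record {r.seq_id!r}: sequence length {len(r.aligned_seq)} "
                    f"!= frame width {self.frame_width}"
                )
            if r.seq_id in seen:
                raise ValueError(f"duplicate seq_id {r.seq_id!r}")
            seen.add(r.seq_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    @property
    def species(self) -> np.ndarray:
        return np.asarray([r.species for r in self.records], dtype=object)

    @property
    def genera(self) -> np.ndarray:
        return np.asarray([r.genus for r in self.records], dtype=object)

    @property
    def orders(self) -> np.ndarray:
        return np.asarray([r.order for r in self.records], dtype=object)

    @property
    def n_species(self) -> int:
        return len(set(r.species for r in self.records))

    def encoded(self) -> np.ndarray:
        """(n_records, frame_width) uint8 code matrix; cached."""
        if self._encoded is None:
            self._encoded = np.vstack([encode_sequence(r.aligned_seq) for r in self.records])
        return self._encoded

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seq_id": [r.seq_id for r in self.records],
                "species": [r.species for r in self.records],
                "genus": [r.genus for r in self.records],
                "order": [r.order for r in self.records],
            }
        )

    def subset(self, keep: Iterable[str]) -> "BarcodeLibrary":
        """New library holding the records whose seq_id is in ``keep`` (order kept)."""
        keep = set(keep)
        return BarcodeLibrary([r for r in self.records if r.seq_id in keep], self.frame_width)

    def species_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r.seq_id)
        return out


def read_library(fasta_path: str | Path, metadata_path: str | Path | None = None) -> BarcodeLibrary:
    """Read an aligned FASTA plus metadata TSV into a :class:`BarcodeLibrary`.

    Without ``metadata_path`` the header convention ``>id|species|genus|order``
    is assumed.  Sequences are uppercased.  Unequal sequence lengths or any
    FASTA/metadata id mismatch raise ``ValueError``.
    """
    seqs: dict[str, str] = {}
    headers: dict[str, str] = {}
    order_of_appearance: list[str] = []
    width: int | None = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        # rec.id truncates at whitespace; keep the full header for the
        # >id|species|genus|order fallback (species names contain spaces)
        sid = rec.description.split("|")[0].split()[0] if "|" in rec.description else rec.id
        s = str(rec.seq).upper()
        if width is None:
            width = len(s)
        elif len(s) != width:
            raise ValueError(
                f"ragged alignment: record {sid!r} has length {len(s)}, expected {width}"
            )
        if sid in seqs:
            raise ValueError(f"duplicate FASTA id {sid!r}")
        seqs[sid] = s
        headers[sid] = rec.description
        order_of_appearance.append(sid)
    if width is None:
        raise ValueError(f"no sequences in {fasta_path}")

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        required = {"seq_id", "species", "genus", "order"}
        if not required.issubset(meta.columns):
            raise ValueError(f"metadata must have columns {sorted(required)}")
        meta_ids = set(meta["seq_id"])
        fasta_ids = set(seqs)
        if meta_ids != fasta_ids:
            missing = sorted(fasta_ids - meta_ids)[:5]
            extra = sorted(meta_ids - fasta_ids)[:5]
            raise ValueError(
                f"FASTA/metadata id mismatch (in FASTA only: {missing}; in metadata only: {extra})"
            )
        info = meta.set_index("seq_id")
        records = [
            BarcodeRecord(
                seq_id=sid,
                species=info.at[sid, "species"],
                genus=info.at[sid, "genus"],
                order=info.at[sid, "order"],
                aligned_seq=seqs[sid],
            )
            for sid in order_of_appearance
        ]
    else:
        records = []
        for sid in order_of_appearance:
            parts = headers[sid].split("|")
            if len(parts) != 4:
                raise ValueError(
                    f"no metadata table and header {headers[sid]!r} is not of the form "
                    "id|species|genus|order"
                )
            records.append(
                BarcodeRecord(
                    seq_id=parts[0].strip(),
                    species=parts[1].strip(),
                    genus=parts[2].strip(),
                    order=parts[3].strip(),
                    aligned_seq=seqs[sid],
                )
            )
    return BarcodeLibrary(records, width)


def write_library(
    lib: BarcodeLibrary, fasta_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write FASTA (60-column wrap) and, when given, the metadata TSV."""
    seq_records = [
        SeqRecord(Seq(r.aligned_seq), id=r.seq_id, description="") for r in lib.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if metadata_path is not None:
        lib.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


#: Default open-nomenclature patterns, applied to the part of the species name
#: after the genus token.  The published filtering rule is open-ended ("sp.,
#: cf., nr. etc."), so the list is configurable.
OPEN_NOMENCLATURE_PATTERNS: tuple[str, ...] = (
    r"^sp\.?($|\s|\d)",
    r"^cf\.?($|\s)",
    r"^nr\.?($|\s)",
    r"^aff\.?($|\s)",
    r"^\d+$",
)


def _is_open_nomenclature(species: str, patterns: Sequence[re.Pattern]) -> bool:
    parts = species.split(maxsplit=1)
    epithet = parts[1] if len(parts) > 1 else ""
    if not epithet:
        return True  # genus-only name carries no species information
    return any(p.search(epithet) for p in patterns)


def filter_records(
    lib: BarcodeLibrary,
    min_length: int = 550,
    drop_open_nomenclature: bool = False,
    patterns: Sequence[str] = OPEN_NOMENCLATURE_PATTERNS,
) -> BarcodeLibrary:
    """Drop short records and, optionally, open-nomenclature species.

    Records with fewer than ``min_length`` determined bases are removed.  With
    ``drop_open_nomenclature`` species epithets matching any of ``patterns``
    (``sp.``, ``cf.``, ``nr.``, ``aff.``, digits-only, ...) are removed too.
    Returns a new library; idempotent.
    """
    if min_length > lib.frame_width:
        raise ValueError(f"min_length {min_length} exceeds frame width {lib.frame_width}")
    compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    kept = []
    for r in lib.records:
        if r.real_length < min_length:
            continue
        if drop_open_nomenclature and _is_open_nomenclature(r.species, compiled):
            continue
        kept.append(r)
    return BarcodeLibrary(kept, lib.frame_width)


def build_dataset(lib: BarcodeLibrary, min_conspecifics: int) -> BarcodeLibrary:
    """Retain species guaranteeing each query ``min_conspecifics`` matches.

    ``min_conspecifics=1`` keeps species with >= 2 records (the dataset-A
    rule), ``2`` keeps species with >= 3 records (dataset-B, required by the
    all-species-barcodes criterion).
    """
    if min_conspecifics < 1:
        raise ValueError("min_conspecifics must be >= 1")
    counts: dict[str, int] = {}
    for r in lib.records:
        counts[r.species] = counts.get(r.species, 0) + 1
    kept = [r for r in lib.records if counts[r.species] >= min_conspecifics + 1]
    return BarcodeLibrary(kept, lib.frame_width)
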